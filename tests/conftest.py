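import numpy as np
import pandas as pd
import pytest

import thermoscope as ts


@pytest.fixture(scope="session")
def default_experiment():
    """One full two-arm ramp simulation plus its analysis, shared read-only."""
    traces, metadata, manifest = ts.generate_experiment(seed=11)
    specs = {
        r.chamber_id: ts.ChamberSpec(r.chamber_id, r.volume_ml / 1000.0, r.animal_mass_g)
        for r in metadata.itertuples()
    }
    rates, report = ts.process_experiment(traces, specs)
    profile, result = ts.analyze_rates(rates)
    return {
        "traces": traces,
        "metadata": metadata,
        "manifest": manifest,
        "specs": specs,
        "rates": rates,
        "report": report,
        "profile": profile,
        "result": result,
    }


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Zero-noise simulation: every stage must round-trip exactly."""
    curve = ts.TrueCurve(between_animal_cv=0.0, sensor_sd=0.0)
    traces, metadata, manifest = ts.generate_experiment(seed=3, curve=curve, n_per_arm=2)
    specs = {
        r.chamber_id: ts.ChamberSpec(r.chamber_id, r.volume_ml / 1000.0, r.animal_mass_g)
        for r in metadata.itertuples()
    }
    rates, _ = ts.process_experiment(traces, specs)
    return {"traces": traces, "manifest": manifest, "specs": specs, "rates": rates}


def make_trace(time, o2, chamber="A", cycle=0, temp=29.0, elapsed_start=0.0):
    return ts.O2Trace(
        chamber_id=chamber,
        cycle_id=cycle,
        nominal_temperature=temp,
        elapsed_start=elapsed_start,
        time=np.asarray(time, dtype=float),
        o2=np.asarray(o2, dtype=float),
    )


@pytest.fixture
def linear_trace():
    """Noiseless 900 s closed phase: o2(t) = 8.0 - 0.001 t."""
    t = np.arange(0.0, 901.0)
    return make_trace(t, 8.0 - 0.001 * t)


def paper_shaped_profile(sd_scale=0.15, n=8):
    """Piecewise-linear profile: plateau <=22, linear rise 22-38, collapse above."""
    temps = np.arange(17.0, 42.0)
    rates = np.array(
        [ts.true_rate(ts.TrueCurve(), t, warm_end=41.0) for t in temps]
    )
    return ts.TemperatureProfile(
        temperature=temps,
        mean_rate=rates,
        sd_rate=sd_scale * rates,
        n=np.full(len(temps), n),
    )
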