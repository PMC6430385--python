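"""Seeded Monte-Carlo validation studies of the full pipeline.

These run the generator and the complete analysis chain many times with
known ground truth and summarize how reliably the pipeline recovers it.
They are ordinary package features (used by the test suite and the
reproduction script) rather than test helpers: a practitioner adapting the
pipeline to a new design can rerun them with their own curve and noise
parameters to see what recovery rates to expect.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import qpcr
from .respirometry import ChamberSpec, process_experiment
from .synthetic import CqScenario, TrueCurve, generate_cq, generate_experiment
from .thermal_window import analyze_rates


def _specs_from_metadata(metadata) -> dict[str, ChamberSpec]:
    return {
        r.chamber_id: ChamberSpec(r.chamber_id, r.volume_ml / 1000.0, r.animal_mass_g)
        for r in metadata.itertuples()
    }


def analyze_simulated_experiment(seed: int, curve: TrueCurve | None = None, **kwargs):
    """Generate one two-arm experiment and run the full analysis on it."""
    traces, metadata, manifest = generate_experiment(seed, curve=curve, **kwargs)
    rates, report = process_experiment(traces, _specs_from_metadata(metadata))
    profile, result = analyze_rates(rates)
    return {
        "manifest": manifest,
        "rates": rates,
        "report": report,
        "profile": profile,
        "result": result,
    }


def ramp_recovery_study(
    n_runs: int = 100,
    base_seed: int = 0,
    curve: TrueCurve | None = None,
    rel_tol: float = 0.10,
) -> dict:
    """Fraction of seeded runs recovering the generating thermal metrics.

    For each run the critical temperatures must match the generating
    breakpoints exactly on the 1 degC measurement grid, and TMMR/TSMR must
    fall within ``rel_tol`` relative error of the generating values.
    """
    if curve is None:
        curve = TrueCurve()
    ct_exact = wt_exact = tmmr_ok = tsmr_ok = 0
    for i in range(n_runs):
        out = analyze_simulated_experiment(base_seed + i, curve=curve)
        r = out["result"]
        ct_exact += r.ct_crit == curve.ct
        wt_exact += r.wt_crit == curve.wt
        tmmr_ok += abs(r.tmmr - curve.tmmr) / curve.tmmr <= rel_tol
        tsmr_ok += abs(r.tsmr - curve.tsmr) / curve.tsmr <= rel_tol
    return {
        "n_runs": n_runs,
        "ct_exact_frac": ct_exact / n_runs,
        "wt_exact_frac": wt_exact / n_runs,
        "tmmr_within_tol_frac": tmmr_ok / n_runs,
        "tsmr_within_tol_frac": tsmr_ok / n_runs,
    }


def null_pvalue_uniformity(
    n_repeats: int = 200,
    base_seed: int = 0,
    n_treated: int = 8,
    n_control: int = 16,
) -> dict:
    """Distribution of exact Mann-Whitney p under a no-fold-change scenario.

    Simulates ``n_repeats`` independent runs with the target expressed
    identically in both groups, computes the exact two-sided p for the
    treated-vs-control CNRQ comparison each time, and scores the collection
    against the uniform distribution with a Kolmogorov-Smirnov test. The
    exact null is discrete, so mild lattice effects are expected; gross
    non-uniformity signals a broken test statistic.
    """
    scenario = CqScenario(
        group_sizes={"control": n_control, "treated": n_treated},
        fold_change={},
    )
    pvalues = []
    for i in range(n_repeats):
        table, _ = generate_cq(scenario, base_seed + i)
        res = qpcr.analyze_cq_table(
            table, ["actb", "18s"], ["hsp70"], comparisons=[("treated", "control")]
        )
        pvalues.append(float(res["comparisons"]["p_value"].iloc[0]))
    ks = stats.kstest(pvalues, "uniform")
    return {
        "n_repeats": n_repeats,
        "pvalues": pvalues,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }
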