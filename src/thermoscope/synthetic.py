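"""Synthetic respirometry traces and Cq tables with known ground truth.

The generator emulates an acute thermal-ramp respirometry experiment on a
sluggish marine invertebrate: animals in 600 mL gas-tight chambers, water
temperature ramped at 2 degC h^-1 from 29 degC up to 41 degC (warm arm) or
down to 17 degC (cold arm), 15 min flush / 15 min closed cycles sampled at
1 Hz, so each closed phase sits on a 1 degC nominal step. The underlying
"true" rate-temperature curve is piecewise linear: a cold plateau at
TSMR below CT_crit, a linear rise to TMMR at WT_crit, and a collapse above.
Chamber O2 declines linearly at (animal + microbial) rate over the
effective water volume, plus i.i.d. Gaussian optode noise; closed phases
are shortened when needed so the trace never falls below 80 % of its
starting (saturation) concentration, mirroring the operational saturation
floor of intermittent-flow protocols.

Every random draw flows from the single ``seed`` argument; identical seeds
give byte-identical CSV output. Each generated dataset ships with a JSON
manifest recording per-cycle true rates so round-trip tests can score the
pipeline against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ThermoscopeError
from .respirometry import (
    PHASE_BLANK_POST,
    PHASE_BLANK_PRE,
    PHASE_MEASURE,
    ChamberSpec,
)


@dataclass(frozen=True)
class RampProtocol:
    """Acute temperature-ramp schedule for one experimental arm."""

    start_temperature: float = 29.0  # degC
    end_temperature: float = 41.0  # degC
    rate_c_per_h: float = 2.0  # magnitude; direction follows end vs start
    flush_minutes: float = 15.0
    measure_minutes: float = 15.0
    sampling_interval: float = 1.0  # s

    def __post_init__(self):
        if self.rate_c_per_h <= 0:
            raise ThermoscopeError("ramp rate magnitude must be positive")
        if self.end_temperature == self.start_temperature:
            raise ThermoscopeError("ramp must change temperature")

    @property
    def temperatures(self) -> np.ndarray:
        """Nominal temperature of each measurement cycle (one per degC)."""
        step = 1.0 if self.end_temperature > self.start_temperature else -1.0
        n = int(round(abs(self.end_temperature - self.start_temperature))) + 1
        return self.start_temperature + step * np.arange(n)

    @property
    def cycle_seconds(self) -> float:
        return (self.flush_minutes + self.measure_minutes) * 60.0


@dataclass(frozen=True)
class TrueCurve:
    """Ground-truth rate-temperature curve and noise model.

    Rates are ug O2 g^-1 h^-1. ``between_animal_cv`` is the coefficient of
    variation of the per-animal multiplicative lognormal scalar;
    ``sensor_sd`` is the optode noise in mg L^-1 per 1 Hz sample;
    ``blank_start``/``blank_end`` are whole-chamber microbial rates
    (mg O2 h^-1) at the pre- and post-trial blank measurements.
    ``rise_shape`` selects a linear rise (the default; rate-temperature
    profiles of this kind correlate near-perfectly linearly) or an
    exponential (constant-Q10) rise for sensitivity tests.
    """

    tsmr: float = 2.2
    tmmr: float = 33.2
    ct: float = 22.0  # degC
    wt: float = 38.0  # degC
    collapse_rate: float = 13.3  # rate at the warm protocol end
    between_animal_cv: float = 0.15
    sensor_sd: float = 0.01
    blank_start: float = 0.02
    blank_end: float = 0.06
    rise_shape: str = "linear"

    def __post_init__(self):
        if self.tmmr <= self.tsmr:
            raise ThermoscopeError("TMMR must exceed TSMR")
        if self.ct >= self.wt:
            raise ThermoscopeError("CT must be below WT")
        if self.between_animal_cv < 0 or self.sensor_sd < 0:
            raise ThermoscopeError("noise parameters must be >= 0")
        if self.rise_shape not in ("linear", "exponential"):
            raise ThermoscopeError(f"unknown rise_shape: {self.rise_shape}")


def true_rate(curve: TrueCurve, temperature: float, warm_end: float = 41.0) -> float:
    """Ground-truth mass-specific rate at ``temperature``.

    Plateau at TSMR below CT, a rise from (CT, TSMR) to (WT, TMMR) — linear
    by default, constant-Q10 exponential when the curve says so — and a
    linear collapse from (WT, TMMR) to (``warm_end``, collapse_rate).
    """
    t = float(temperature)
    if t <= curve.ct:
        return curve.tsmr
    if t <= curve.wt:
        frac = (t - curve.ct) / (curve.wt - curve.ct)
        if curve.rise_shape == "exponential":
            return curve.tsmr * (curve.tmmr / curve.tsmr) ** frac
        return curve.tsmr + frac * (curve.tmmr - curve.tsmr)
    if warm_end == curve.wt:
        return curve.tmmr
    frac = (t - curve.wt) / (warm_end - curve.wt)
    return curve.tmmr + frac * (curve.collapse_rate - curve.tmmr)


def _animal_scalar(rng: np.random.Generator, cv: float) -> float:
    """Lognormal scalar with unit mean and the given CV."""
    if cv == 0:
        return 1.0
    sigma2 = math.log(1.0 + cv**2)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def _phase_samples(
    rng: np.random.Generator,
    initial_o2: float,
    decline_per_s: float,
    duration: float,
    dt: float,
    sensor_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(0.0, duration + dt / 2, dt)
    o2 = initial_o2 - decline_per_s * t
    if sensor_sd > 0:
        o2 = o2 + rng.normal(0.0, sensor_sd, size=len(t))
    return t, np.maximum(o2, 1e-6)


def generate_traces(
    protocol: RampProtocol,
    curve: TrueCurve,
    chambers: list[ChamberSpec],
    seed: int,
    *,
    initial_o2: float = 6.5,
    min_phase_seconds: float = 180.0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one ramp arm for a set of chambers.

    Timeline per chamber: a 15 min pre-blank on the empty chamber, a 1 h
    acclimation gap, one flush+closed cycle per nominal degree, then a
    post-blank. The closed-phase concentration declines at
    (animal + interpolated microbial) rate over the effective water volume;
    the phase is shortened whenever a full-length phase would deplete below
    80 % of ``initial_o2``, and generation fails if even
    ``min_phase_seconds`` would.

    Returns the long-format trace table (schema of
    :data:`thermoscope.respirometry.TRACE_COLUMNS`) and a manifest with the
    per-cycle true rates.
    """
    rng = np.random.default_rng(seed)
    temps = protocol.temperatures
    measure_s = protocol.measure_minutes * 60.0
    flush_s = protocol.flush_minutes * 60.0
    dt = protocol.sampling_interval
    t_cycles0 = measure_s + 3600.0  # pre-blank + acclimation before first flush
    t_post = t_cycles0 + len(temps) * protocol.cycle_seconds + measure_s
    pre_mid, post_mid = measure_s / 2.0, t_post + measure_s / 2.0

    def blank_at(t: float) -> float:
        frac = (t - pre_mid) / (post_mid - pre_mid)
        return curve.blank_start + frac * (curve.blank_end - curve.blank_start)

    frames = []
    manifest_chambers = []
    for spec in chambers:
        scalar = _animal_scalar(rng, curve.between_animal_cv)
        cycles = []
        # pre-blank (empty chamber: full volume)
        for phase, start in ((PHASE_BLANK_PRE, 0.0), (PHASE_BLANK_POST, t_post)):
            rate = blank_at(start + measure_s / 2.0)
            decline = rate / (spec.volume * 3600.0)
            t, o2 = _phase_samples(rng, initial_o2, decline, measure_s, dt, curve.sensor_sd)
            frames.append(
                pd.DataFrame(
                    {
                        "chamber_id": spec.chamber_id,
                        "cycle_id": -1 if phase == PHASE_BLANK_PRE else len(temps),
                        "phase": phase,
                        "nominal_temperature_c": protocol.start_temperature,
                        "elapsed_s": start + t,
                        "time_s": t,
                        "o2_mg_per_l": o2,
                    }
                )
            )
        for k, temp in enumerate(temps):
            start = t_cycles0 + k * protocol.cycle_seconds + flush_s
            rate_animal = scalar * true_rate(curve, temp, warm_end=temps[-1])

            def decline_for(duration: float) -> tuple[float, float]:
                blank = blank_at(start + duration / 2.0)
                total_mg_h = rate_animal * spec.animal_mass / 1000.0 + blank
                return total_mg_h / (spec.effective_volume * 3600.0), blank

            decline, blank = decline_for(measure_s)
            duration = measure_s
            if decline > 0:
                max_duration = 0.2 * initial_o2 / decline
                if max_duration < min_phase_seconds:
                    raise ThermoscopeError(
                        f"chamber {spec.chamber_id} at {temp} degC: depletion too "
                        "fast for any feasible closed phase"
                    )
                duration = min(measure_s, math.floor(max_duration))
                # re-anchor the microbial term to the shortened phase midpoint
                decline, blank = decline_for(duration)
            t, o2 = _phase_samples(rng, initial_o2, decline, duration, dt, curve.sensor_sd)
            frames.append(
                pd.DataFrame(
                    {
                        "chamber_id": spec.chamber_id,
                        "cycle_id": k,
                        "phase": PHASE_MEASURE,
                        "nominal_temperature_c": temp,
                        "elapsed_s": start + t,
                        "time_s": t,
                        "o2_mg_per_l": o2,
                    }
                )
            )
            cycles.append(
                {
                    "cycle_id": k,
                    "temperature_c": float(temp),
                    "true_rate_ug_per_g_h": rate_animal,
                    "blank_mg_per_h": blank,
                    "duration_s": duration,
                }
            )
        manifest_chambers.append(
            {
                "chamber_id": spec.chamber_id,
                "animal_mass_g": spec.animal_mass,
                "volume_l": spec.volume,
                "animal_scalar": scalar,
                "cycles": cycles,
            }
        )
    traces = pd.concat(frames, ignore_index=True)
    manifest = {
        "seed": seed,
        "protocol": asdict(protocol),
        "curve": asdict(curve),
        "initial_o2_mg_per_l": initial_o2,
        "chambers": manifest_chambers,
    }
    return traces, manifest


def default_chambers(
    prefix: str,
    n: int,
    rng: np.random.Generator,
    *,
    volume: float = 0.600,
    mass_mean: float = 63.0,
    mass_sd: float = 15.0,
) -> list[ChamberSpec]:
    """Chambers with one juvenile animal each; masses ~ N(63, 15) g, clipped."""
    masses = np.clip(rng.normal(mass_mean, mass_sd, size=n), 25.0, 120.0)
    return [
        ChamberSpec(chamber_id=f"{prefix}{i + 1}", volume=volume, animal_mass=float(m))
        for i, m in enumerate(masses)
    ]


def generate_experiment(
    seed: int,
    curve: TrueCurve | None = None,
    n_per_arm: int = 8,
    *,
    warm_end: float = 41.0,
    cold_end: float = 17.0,
    start: float = 29.0,
    initial_o2: float = 6.5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full two-arm design: a warm ramp and a cold ramp, n animals each.

    Returns (traces, chamber metadata table, manifest). Chamber ids are
    W1..Wn for the warm arm and C1..Cn for the cold arm; the 29 degC cycle
    is measured by both arms, as when ramps start from a common acclimation
    temperature.
    """
    if curve is None:
        curve = TrueCurve()
    rng = np.random.default_rng(seed)
    warm_seed, cold_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    warm_protocol = RampProtocol(start_temperature=start, end_temperature=warm_end)
    cold_protocol = RampProtocol(start_temperature=start, end_temperature=cold_end)
    warm_chambers = default_chambers("W", n_per_arm, rng)
    cold_chambers = default_chambers("C", n_per_arm, rng)
    warm_traces, warm_manifest = generate_traces(
        warm_protocol, curve, warm_chambers, warm_seed, initial_o2=initial_o2
    )
    cold_traces, cold_manifest = generate_traces(
        cold_protocol, curve, cold_chambers, cold_seed, initial_o2=initial_o2
    )
    traces = pd.concat([warm_traces, cold_traces], ignore_index=True)
    metadata = pd.DataFrame(
        {
            "chamber_id": [c.chamber_id for c in warm_chambers + cold_chambers],
            "volume_ml": [c.volume * 1000.0 for c in warm_chambers + cold_chambers],
            "animal_mass_g": [c.animal_mass for c in warm_chambers + cold_chambers],
        }
    )
    manifest = {
        "seed": seed,
        "curve": asdict(curve),
        "warm": warm_manifest,
        "cold": cold_manifest,
    }
    return traces, metadata, manifest


# ---------------------------------------------------------------------------
# Cq-table generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    role: str  # "target" | "reference"
    baseline_cq: float
    efficiency: float = 2.0


@dataclass(frozen=True)
class CqScenario:
    """Design of a simulated qPCR run.

    Defaults emulate a heat/cold-shock expression experiment: one inducible
    target over two stable reference genes, three technical replicates,
    n = 8 treated animals per arm against a pooled control of 16. Fold
    changes are multiplicative on expression, so a fold F shifts the target
    Cq by -log_E(F). ``biological_sd`` (cycles) is per-sample variation of
    the target; ``reference_instability_sd`` perturbs reference genes per
    sample; ``technical_sd`` applies to every replicate well.
    """

    genes: Mapping[str, GeneSpec] = field(
        default_factory=lambda: {
            "hsp70": GeneSpec("target", 28.0),
            "actb": GeneSpec("reference", 24.0),
            "18s": GeneSpec("reference", 12.0),
        }
    )
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control_29C": 16, "heat_41C": 8, "cold_17C": 8}
    )
    fold_change: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "heat_41C": {"hsp70": 20.0},
            "cold_17C": {"hsp70": 1.2},
        }
    )
    n_technical: int = 3
    technical_sd: float = 0.15
    reference_instability_sd: float = 0.2
    biological_sd: float = 1.0

    def __post_init__(self):
        for group, folds in self.fold_change.items():
            for gene, f in folds.items():
                if f <= 0:
                    raise ThermoscopeError(f"fold change for {gene} in {group} must be > 0")
        if min(self.technical_sd, self.reference_instability_sd, self.biological_sd) < 0:
            raise ThermoscopeError("scenario noise sds must be >= 0")

    @property
    def reference_genes(self) -> list[str]:
        return [g for g, s in self.genes.items() if s.role == "reference"]

    @property
    def target_genes(self) -> list[str]:
        return [g for g, s in self.genes.items() if s.role == "target"]


def generate_cq(scenario: CqScenario, seed: int) -> tuple[pd.DataFrame, dict]:
    """Simulate a Cq table for the scenario; returns (table, manifest).

    Target Cq for a sample in group g:
    ``baseline - log_E(fold_g) + N(0, biological_sd) + N(0, technical_sd)``
    per replicate well; reference genes get per-sample instability noise
    instead of the biological term.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in scenario.group_sizes.items():
        for i in range(n):
            sample_id = f"{group}_s{i + 1}"
            for gene, gspec in scenario.genes.items():
                if gspec.role == "target":
                    fold = scenario.fold_change.get(group, {}).get(gene, 1.0)
                    shift = -math.log(fold) / math.log(gspec.efficiency)
                    sample_cq = (
                        gspec.baseline_cq
                        + shift
                        + rng.normal(0.0, scenario.biological_sd)
                    )
                else:
                    sample_cq = gspec.baseline_cq + rng.normal(
                        0.0, scenario.reference_instability_sd
                    )
                for rep in range(scenario.n_technical):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "gene": gene,
                            "replicate": rep + 1,
                            "cq": sample_cq + rng.normal(0.0, scenario.technical_sd),
                        }
                    )
    table = pd.DataFrame(rows)
    manifest = {
        "seed": seed,
        "genes": {g: asdict(s) for g, s in scenario.genes.items()},
        "group_sizes": dict(scenario.group_sizes),
        "true_fold_change": {g: dict(f) for g, f in scenario.fold_change.items()},
        "noise": {
            "technical_sd": scenario.technical_sd,
            "reference_instability_sd": scenario.reference_instability_sd,
            "biological_sd": scenario.biological_sd,
        },
    }
    return table, manifest
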