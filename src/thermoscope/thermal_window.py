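"""Thermal-window metrics from per-temperature oxygen consumption rates.

During an acute temperature ramp an ectotherm's oxygen consumption rate
(OCR) typically shows a cold plateau, a quasi-linear rise with temperature,
and a collapse past a warm critical point. This module aggregates replicate
rates into a temperature profile and derives:

* the linear window [CT_crit, WT_crit] of the OCR-temperature relationship,
* TMMR (temperature-induced maximal metabolic rate) at WT_crit and
  TSMR (temperature-induced standard metabolic rate) at CT_crit,
* TAS = TMMR - TSMR, the temperature-induced aerobic scope,
* Q10 = (R2/R1)^(10/(T2-T1)) over the cold and warm arms, and
* the midpoint construction: the rate halfway between TSMR and TMMR and the
  temperature at which the window regression attains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoLinearWindowError, ThermoscopeError

# warning codes
N_EQ_1 = "N_EQ_1"
NON_PEAK = "NON_PEAK"
NO_PLATEAU = "NO_PLATEAU"
CENSORED_PEAK = "CENSORED_PEAK"
NO_CONTROL_TEMPERATURE = "NO_CONTROL_TEMPERATURE"


@dataclass(frozen=True)
class TemperatureProfile:
    """Per-temperature mean +/- sd rate across QC-passing replicates."""

    temperature: np.ndarray  # degC, unique and sorted
    mean_rate: np.ndarray  # ug O2 g^-1 h^-1
    sd_rate: np.ndarray
    n: np.ndarray
    warnings: tuple = field(default_factory=tuple)

    def __post_init__(self):
        for name in ("temperature", "mean_rate", "sd_rate", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        t = self.temperature
        if len(t) == 0:
            raise ThermoscopeError("temperature profile is empty")
        if len(np.unique(t)) != len(t) or not np.all(np.diff(t) > 0):
            raise ThermoscopeError("profile temperatures must be unique and sorted")
        if np.any(self.n < 1) or np.any(self.sd_rate < 0):
            raise ThermoscopeError("profile requires n >= 1 and sd >= 0 per row")

    def __len__(self) -> int:
        return len(self.temperature)

    def rate_at(self, temperature: float) -> float:
        idx = np.nonzero(np.isclose(self.temperature, temperature))[0]
        if len(idx) == 0:
            raise KeyError(f"temperature {temperature} not in profile")
        return float(self.mean_rate[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_c": self.temperature,
                "mean_rate_ug_per_g_h": self.mean_rate,
                "sd_rate_ug_per_g_h": self.sd_rate,
                "n": self.n.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemperatureProfile":
        df = df.sort_values("temperature_c")
        return cls(
            temperature=df["temperature_c"].to_numpy(),
            mean_rate=df["mean_rate_ug_per_g_h"].to_numpy(),
            sd_rate=df["sd_rate_ug_per_g_h"].to_numpy(),
            n=df["n"].to_numpy(),
        )


@dataclass(frozen=True)
class LinearWindow:
    """Accepted linear OCR-temperature range with its OLS fit."""

    t_low: float
    t_high: float
    slope: float  # ug O2 g^-1 h^-1 per degC
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, temperature: float) -> float:
        return self.slope * temperature + self.intercept


@dataclass(frozen=True)
class ThermalWindowResult:
    """Full set of thermal-window metrics for one ramp experiment."""

    tmmr: float
    wt_crit: float
    tsmr: float
    ct_crit: float
    tas: float
    q10_cold: float
    q10_warm: float
    r_mid: float
    t_opt: float
    band_rate_low: float
    band_rate_high: float
    band_t_low: float
    band_t_high: float
    window: LinearWindow
    warnings: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "tmmr_ug_per_g_h": self.tmmr,
            "wt_crit_c": self.wt_crit,
            "tsmr_ug_per_g_h": self.tsmr,
            "ct_crit_c": self.ct_crit,
            "tas_ug_per_g_h": self.tas,
            "q10_cold": self.q10_cold,
            "q10_warm": self.q10_warm,
            "r_mid_ug_per_g_h": self.r_mid,
            "t_opt_c": self.t_opt,
            "optimal_band": {
                "rate_low": self.band_rate_low,
                "rate_high": self.band_rate_high,
                "t_low": self.band_t_low,
                "t_high": self.band_t_high,
            },
            "window": {
                "t_low": self.window.t_low,
                "t_high": self.window.t_high,
                "slope": self.window.slope,
                "intercept": self.window.intercept,
                "r_squared": self.window.r_squared,
                "n_points": self.window.n_points,
            },
            "warnings": list(self.warnings),
        }


def aggregate_profile(rates: pd.DataFrame) -> TemperatureProfile:
    """Per-temperature mean, sample sd (n-1) and n over QC-passing rates.

    QC-failing rows are excluded from the aggregation but counted; a
    temperature with a single replicate reports sd = 0 and the N_EQ_1 flag.
    """
    if rates.empty:
        raise ThermoscopeError("no rate records to aggregate")
    passing = rates[rates["qc_pass"].astype(bool)]
    if passing.empty:
        raise ThermoscopeError("no QC-passing rate records to aggregate")
    warnings = []
    n_excluded = len(rates) - len(passing)
    if n_excluded:
        warnings.append(f"EXCLUDED_{n_excluded}_QC_FAIL")
    grp = passing.groupby("nominal_temperature_c")["rate_ug_per_g_h"]
    agg = grp.agg(["mean", "std", "count"]).sort_index()
    sd = agg["std"].fillna(0.0).to_numpy()
    if np.any(agg["count"].to_numpy() == 1):
        warnings.append(N_EQ_1)
    return TemperatureProfile(
        temperature=agg.index.to_numpy(),
        mean_rate=agg["mean"].to_numpy(),
        sd_rate=sd,
        n=agg["count"].to_numpy(),
        warnings=tuple(warnings),
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def find_linear_window(
    profile: TemperatureProfile,
    r2_min: float = 0.98,
    min_span: int = 4,
    rise_fraction: float = 0.25,
) -> LinearWindow:
    """Locate the rising limb [plateau onset, peak] and fit it by OLS.

    The window's warm boundary is the profile's global maximum (the peak of
    the rate-temperature curve). The cold boundary is the plateau onset,
    found from the forward differences of the per-temperature means below
    the peak: steps within the cold plateau are near zero while steps on
    the rising limb are of the order of the rise slope, so the first
    difference exceeding ``rise_fraction`` times the largest sub-peak step
    marks the onset. This breakpoint scan is what pins the window to the
    plateau edge: a global goodness-of-fit criterion alone barely moves
    when a wide, steep window absorbs one or two flat plateau points, so
    selecting the widest range above an R^2 threshold systematically
    overshoots the breakpoint.

    The accepted window must span at least ``min_span`` temperatures, have
    a positive OLS slope, and reach R^2 >= ``r2_min`` on the
    per-temperature means; otherwise :class:`NoLinearWindowError` is
    raised.
    """
    t, m = profile.temperature, profile.mean_rate
    if len(t) < min_span:
        raise NoLinearWindowError(
            f"profile has {len(t)} temperatures; need at least {min_span}"
        )
    i_peak = int(np.argmax(m))
    if i_peak == 0:
        raise NoLinearWindowError("profile peaks at its cold edge: no rising limb")
    steps = np.diff(m[: i_peak + 1])
    positive = steps[steps > 0]
    if len(positive) == 0:
        raise NoLinearWindowError("no rising steps below the profile peak")
    threshold = rise_fraction * float(positive.max())
    i_low = int(np.nonzero(steps >= threshold)[0][0])
    if i_peak - i_low + 1 < min_span:
        raise NoLinearWindowError(
            f"rising limb spans only {i_peak - i_low + 1} temperatures; "
            f"need at least {min_span}"
        )
    sl, ic, r2 = _ols(t[i_low : i_peak + 1], m[i_low : i_peak + 1])
    if sl <= 0:
        raise NoLinearWindowError("rising limb has non-positive OLS slope")
    if r2 < r2_min:
        raise NoLinearWindowError(
            f"rising limb [{t[i_low]:g}, {t[i_peak]:g}] fits with R^2 = {r2:.4f} "
            f"< {r2_min}; consider relaxing r2_min"
        )
    return LinearWindow(
        t_low=float(t[i_low]),
        t_high=float(t[i_peak]),
        slope=sl,
        intercept=ic,
        r_squared=r2,
        n_points=i_peak - i_low + 1,
    )


@dataclass(frozen=True)
class ThermalExtremes:
    tmmr: float
    wt_crit: float
    tsmr: float
    ct_crit: float
    warnings: tuple


def detect_extremes(
    profile: TemperatureProfile,
    window: LinearWindow,
    plateau_tol: float | None = None,
) -> ThermalExtremes:
    """Locate TMMR/WT_crit and TSMR/CT_crit on an aggregated profile.

    TMMR is the global maximum mean rate and WT_crit its temperature; rates
    above WT_crit must be strictly lower (NON_PEAK warning otherwise) and a
    peak at the profile's warm edge is flagged CENSORED_PEAK because no
    decline was observed. TSMR anchors to the window's cold boundary (the
    onset of the metabolic stable state) rather than the global minimum,
    since sub-plateau rates can dip below the stable-state level. Plateau
    rates below CT_crit must sit within ``plateau_tol`` (default: one sd of
    the CT_crit row) of TSMR, else NO_PLATEAU is warned.
    """
    warnings = []
    t, m = profile.temperature, profile.mean_rate
    imax = int(np.argmax(m))
    tmmr, wt_crit = float(m[imax]), float(t[imax])
    if imax == len(t) - 1:
        warnings.append(CENSORED_PEAK)
    elif np.any(m[imax + 1 :] >= tmmr):
        warnings.append(NON_PEAK)
    ct_crit = window.t_low
    tsmr = profile.rate_at(ct_crit)
    below = t < ct_crit
    if np.any(below):
        if plateau_tol is None:
            plateau_tol = float(profile.sd_rate[np.isclose(t, ct_crit)][0])
        if np.any(np.abs(m[below] - tsmr) > plateau_tol):
            warnings.append(NO_PLATEAU)
    return ThermalExtremes(tmmr, wt_crit, tsmr, ct_crit, tuple(warnings))


def compute_tas(tmmr: float, tsmr: float) -> float:
    """Temperature-induced aerobic scope: TAS = TMMR - TSMR."""
    if tmmr < tsmr:
        raise ThermoscopeError(
            "TMMR below TSMR: window detection failed upstream"
        )
    return tmmr - tsmr


def compute_q10(r1: float, r2: float, t1: float, t2: float) -> float:
    """Temperature quotient Q10 = (R2/R1)^(10/(T2-T1)).

    Swapping both endpoints leaves Q10 unchanged, and Q10 is invariant to a
    common rescaling of the two rates.
    """
    if r1 <= 0 or r2 <= 0:
        raise ThermoscopeError("Q10 requires strictly positive rates")
    if t1 == t2:
        raise ThermoscopeError("Q10 requires distinct temperatures")
    return float((r2 / r1) ** (10.0 / (t2 - t1)))


def thermal_optimum(
    tmmr: float,
    tsmr: float,
    window: LinearWindow,
    acclimation_temperature: float = 29.0,
) -> tuple[float, float, tuple[float, float, float, float]]:
    """Midpoint rate, its temperature, and the optimal performance band.

    ``r_mid = (TMMR + TSMR) / 2`` is the rate at which equal aerobic
    headroom exists toward the warm and cold limits; ``t_opt`` is the
    temperature at which the window regression attains it, clamped to the
    window. The band spans from the regression rate at the acclimation
    temperature up to ``r_mid``, with the corresponding temperature bounds.
    """
    if window.slope <= 0:
        raise ThermoscopeError("thermal optimum requires a positive window slope")
    r_mid = (tmmr + tsmr) / 2.0
    t_opt = (r_mid - window.intercept) / window.slope
    t_opt = min(max(t_opt, window.t_low), window.t_high)
    r_accl = window.predict(acclimation_temperature)
    band = (r_accl, r_mid, acclimation_temperature, t_opt)
    return r_mid, float(t_opt), band


def analyze_profile(
    profile: TemperatureProfile,
    *,
    r2_min: float = 0.98,
    min_span: int = 4,
    rise_fraction: float = 0.25,
    plateau_tol: float | None = None,
    acclimation_temperature: float = 29.0,
) -> ThermalWindowResult:
    """Run window detection and all thermal metrics on one profile.

    Q10 is computed between the acclimation (control) temperature and each
    critical temperature, using the profile's measured mean rate at the
    acclimation temperature (the window regression value is substituted,
    with a warning, if that temperature was not measured).
    """
    window = find_linear_window(profile, r2_min, min_span, rise_fraction)
    extremes = detect_extremes(profile, window, plateau_tol)
    warnings = list(profile.warnings) + list(extremes.warnings)
    tas = compute_tas(extremes.tmmr, extremes.tsmr)
    try:
        r_control = profile.rate_at(acclimation_temperature)
    except KeyError:
        r_control = window.predict(acclimation_temperature)
        warnings.append(NO_CONTROL_TEMPERATURE)
    q10_warm = compute_q10(r_control, extremes.tmmr, acclimation_temperature, extremes.wt_crit)
    q10_cold = compute_q10(r_control, extremes.tsmr, acclimation_temperature, extremes.ct_crit)
    r_mid, t_opt, band = thermal_optimum(
        extremes.tmmr, extremes.tsmr, window, acclimation_temperature
    )
    return ThermalWindowResult(
        tmmr=extremes.tmmr,
        wt_crit=extremes.wt_crit,
        tsmr=extremes.tsmr,
        ct_crit=extremes.ct_crit,
        tas=tas,
        q10_cold=q10_cold,
        q10_warm=q10_warm,
        r_mid=r_mid,
        t_opt=t_opt,
        band_rate_low=band[0],
        band_rate_high=band[1],
        band_t_low=band[2],
        band_t_high=band[3],
        window=window,
        warnings=tuple(warnings),
    )


def analyze_rates(rates: pd.DataFrame, **kwargs) -> tuple[TemperatureProfile, ThermalWindowResult]:
    """Convenience: aggregate a rates table and analyze the profile."""
    profile = aggregate_profile(rates)
    return profile, analyze_profile(profile, **kwargs)
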