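# Methods

This note documents the models, defaults and numerical choices behind the
thermoscope pipeline, and what the synthetic-data tests do and do not show
about real measurements.

## Respirometry model

Intermittent-flow respirometry alternates flush phases with closed phases
in which the dissolved-O₂ concentration of a sealed chamber declines. The
closed-phase model is ideal mixing: concentration falls linearly at
`(animal rate + microbial rate) / V_eff`, where `V_eff` is the chamber
volume minus the animal's displacement (mass / density, density default
1.0 g mL⁻¹; at ~63 g in a 600 mL chamber this is a ~10 % correction).
Rates are converted as

```
whole-chamber rate [mg h⁻¹]   = −slope · V_eff · 3600
corrected rate                = whole-chamber − blank(t_mid)
mass-specific rate [µg g⁻¹ h⁻¹] = corrected · 1000 / mass
```

We use the water volume rather than the nominal chamber volume because the
concentration-to-amount conversion physically happens through the water
phase; analyses that use the chamber volume instead will report rates
~10 % higher at these animal sizes.

**Edge trimming.** The first and last 60 s of each closed phase are
excluded before fitting — the opening carries flush/mixing transients and
the closing minute can be affected by accumulating gradients.

**Minute binning.** The OLS slope is fitted on 60-s bin means rather than
raw 1 Hz samples. Binning leaves the slope estimate essentially unchanged,
but R² is a signal-to-noise quantity that depends on sampling granularity:
a shallow decline of ~2 µg g⁻¹ h⁻¹ is invisible sample-to-sample at 1 Hz
(raw R² far below any sensible gate even for a perfectly clean signal) yet
unambiguous on minute means. The R² ≥ 0.90 quality gate is therefore
applied at the minute scale, where it discriminates broken traces from
shallow ones rather than simply rejecting every low rate. Partial trailing
bins are dropped so all bin means carry equal variance; a lone-sample bin
would otherwise dominate the residual sum and spuriously fail shallow
slopes — this also matters statistically, because such failures select
against low-rate replicates and bias the cold-plateau mean upward.

**Blank correction.** Microbial background is measured in the empty
chamber before animals are introduced and after they are removed (each a
15-min run, processed with the same trim/bin/fit chain but converted
through the full chamber volume). Background at any time during the trial
is the linear interpolation between the two, indexed by elapsed experiment
time at the closed-phase midpoint and clamped outside the measured span.
Slightly positive blank slopes (apparent O₂ production from sensor drift)
are clamped to a zero rate. Temperature dependence of the microbial rate is
folded into this time interpolation, as is conventional when per-temperature
blanks are unavailable.

**QC policy.** Records failing any gate (R² < 0.90, minimum saturation
< 0.80 of the reference concentration, trace too short to trim, negative
corrected rate) are flagged with reason codes and written to the output;
they are excluded from aggregation but never silently dropped, and the QC
report's counts reconcile with the flagged rows. A zero-variance trace has
no defined correlation; its R² is reported as 0 so it fails the gate
deterministically rather than propagating NaN. When no 100 %-saturation
reference concentration is configured, the trace's first sample is used
and the saturation gate degrades to a relative-decline check.

## Thermal-window detection

Per-temperature profiles are means ± sample sd (n−1) over QC-passing
replicates, as plotted in this literature; replicate spread enters the
plateau tolerance and reporting but not the window fit.

The rate–temperature curve is treated as piecewise linear: cold plateau,
rising limb, collapse past the peak. The window's warm boundary is the
global maximum of the profile (WT_crit, rate TMMR). The cold boundary
(CT_crit) is the plateau onset, found from forward differences of the
means below the peak: plateau steps are near zero, rising-limb steps are
of the order of the rise slope, and the first difference exceeding
`rise_fraction` (default 0.25) of the largest sub-peak step marks the
onset. A breakpoint scan is used deliberately instead of "the widest
window whose overall R² clears a threshold": with a steep rise over a wide
range, absorbing one or two flat plateau points moves the global R² by
only ~0.01, so an R²-gated widest-window rule systematically overshoots
the breakpoint (on a noiseless plateau/22–38/collapse profile it returns
19–38 °C at R² = 0.986 with a 0.98 gate). The difference scan recovers
breakpoints exactly on noiseless piecewise profiles and is robust to the
dominant noise mode of ramp designs, where each arm carries its own
animals and the profile can kink where the arms join; the first
plateau-to-rise jump lies entirely within the cold arm and is unaffected.

The accepted window must span ≥ `min_span` (4) temperatures, fit with a
positive OLS slope and reach R² ≥ `r2_min` on the means. The published
window R² of ~0.99 is a result, not a criterion; the default acceptance
threshold is 0.98 to tolerate replicate noise, and failing it raises an
explicit no-window error (CLI exit code 2).

TSMR anchors to the window's cold boundary — the start of the metabolic
stable state — rather than to the global minimum, because sub-plateau
rates may dip below the stable-state level. Warnings flag a peak at the
profile's warm edge (no decline observed, `CENSORED_PEAK`), non-strict
peaks (`NON_PEAK`), and plateau points deviating from TSMR by more than
`plateau_tol` (default: one sd of the CT_crit row; `NO_PLATEAU`).

Derived metrics: `TAS = TMMR − TSMR`; `Q10 = (R2/R1)^(10/(T2−T1))`
computed between the acclimation temperature (default 29 °C, using the
measured mean there) and each critical endpoint; the midpoint rate
`r_mid = (TMMR + TSMR)/2` with its temperature `t_opt` from inverting the
window regression (clamped to the window), plus the band from the
regression rate at the acclimation temperature up to `r_mid`. Q₁₀ values
are stored at full precision and rounded to one decimal in summaries.
`t_opt` is a geometric construct of this procedure, not a claim about the
organism's optimum. Note that on the published group means the Q₁₀
formula gives 12.9 for the cold arm while the source tabulates 13.2, and
the midpoint rate is (33.2+2.2)/2 = 17.7 while the source prints 18.7;
the pipeline reports the formula values.

## Synthetic data

`generate_experiment` emulates the two-arm acute-ramp design: warm ramp
29→41 °C and cold ramp 29→17 °C at 2 °C h⁻¹, 15 min flush / 15 min closed
cycles sampled at 1 Hz, one closed phase per 1 °C nominal step, 8 animals
per arm in 600 mL chambers with masses ~ N(63, 15) g (clipped to
25–120 g), each arm preceded and followed by an empty-chamber blank run.

The generating curve defaults to the plateau–rise–collapse shape with
TSMR = 2.2 and TMMR = 33.2 µgO₂ g⁻¹ h⁻¹ at CT = 22 °C and WT = 38 °C,
collapsing to 13.3 at 41 °C. The rise is linear (matching the near-perfect
linear correlation such profiles show); per-animal variation is a single
multiplicative lognormal scalar with CV 0.15 — multiplicative because
rates are positive and reported SDs scale with means (≈14 % at the peak,
≈20 % at the control temperature), and a single persistent scalar because
each animal keeps its metabolic identity across its arm. Microbial blanks
drift linearly from 0.02 to 0.06 mg h⁻¹ over the experiment; optode noise
is i.i.d. Gaussian with sd 0.01 mg L⁻¹ per 1 Hz sample (a calibration
choice at the precision scale of optical O₂ meters; real instruments'
noise levels are rarely reported). Closed phases are shortened whenever a
full 15 min would deplete the chamber below 80 % of the starting
concentration, mirroring the operational saturation floor, and generation
fails if no feasible duration exists. All randomness flows from the single
seed; identical seeds give byte-identical CSV output, and a JSON manifest
records every per-cycle true rate.

`generate_cq` emulates the expression design: one heat-inducible target
(hsp70, baseline Cq 28) over two stable references (actb at 24, 18S at
12), three technical replicates, n = 8 per treatment against a pooled
control of 16. A fold change F shifts the target Cq by −log_E(F); noise
is per-sample biological sd 1.0 cycle on the target (wide, matching the
roughly five-fold 95 % CIs typical of such data), per-sample reference
instability sd 0.2 and per-well technical sd 0.15 cycles. Default folds
are 20 for the heat group and 1.2 (undetectable at these n) for the cold
group.

**What the generator does not emulate:** temperature-dependent O₂
solubility (the initial concentration is a constant 6.5 mg L⁻¹),
autocorrelated sensor drift, mixing transients, activity-driven rate
excursions, chamber-to-chamber sensor differences, and reference genes
that respond to treatment. Passing round-trip tests therefore demonstrate
the correctness of the estimation chain under the stated model, not
robustness to every artifact of real recordings.

## qPCR quantification

Technical replicates are averaged on the Cq scale (replicate sd > 0.5
cycles warns, never silently excludes). Relative quantities use
`RQ = E^(Cq̄_gene − Cq)` against the gene's run mean, with per-gene
efficiency from a dilution-series slope (`E = 10^(−1/slope)`) when
supplied and E = 2.0 (perfect doubling) otherwise. The per-sample
normalization factor is the geometric mean of ≥ 2 reference-gene RQs;
NRQ = RQ_target / NF; CNRQ rescales NRQ by the geometric mean over the
calibration set — all samples by default, which is why control-group mean
CNRQs need not equal 1. Calibration only rescales: between-sample CNRQ
ratios are invariant to it, so ratios and significance structure are the
meaningful outputs. Absolute CNRQ values from vendor software cannot be
matched without the underlying raw Cq data.

geNorm stability is the mean sd of pairwise log₂ expression ratios with
the other candidates; genes with M ≥ 0.5 are flagged unstable. Group
summaries are geometric means with t-based 95 % CIs on the log₂ scale,
back-transformed — hence multiplicatively symmetric
(`high/mean = mean/low`), as published intervals of this kind are.
Group comparisons use a two-sided Mann–Whitney test: exact null
distribution whenever the smaller group has ≤ 10 observations and the
data are tie-free, otherwise the normal approximation with tie and
continuity corrections. Two identical samples return p = 1 by convention.
The exact null is discrete, so p-value uniformity checks against the
continuous uniform are slightly conservative. Significance stars follow
the 0.05/0.01 convention. Treatment-vs-pooled-control designs are
expressed through a configurable group-pooling map, not hard-coded.

## Validation studies

`thermoscope.validation` packages two seeded Monte-Carlo studies run by
the test suite and the reproduction script, at problem sizes chosen to
give stable fractions at desk scale: a 100-run recovery study (each run a
full two-arm experiment at default noise, scoring exact grid recovery of
CT/WT and 10 % relative recovery of TMMR/TSMR) and a 200-repeat
null-uniformity study of the exact Mann–Whitney p under a no-fold-change
scenario. With default noise the recovery study typically lands at 100 %
for both critical temperatures and ~92–94 % for the extremes — the
extremes' error is dominated by the sampling spread of the 8-animal mean
scalar (sd ≈ CV/√8 ≈ 5.3 %), so ~10 % of runs falling outside ±10 % is the
statistically expected behavior of the design itself, not estimator noise.

## Known limitations

* One animal per chamber is assumed; designs with shared chambers need
  their rates disaggregated upstream.
* Blank correction assumes the microbial rate varies linearly in time;
  strongly temperature-coupled microbial growth would violate this.
* The window fit uses per-temperature means; replicate-level regression
  (with its different weighting) is not implemented.
* No parametric thermal-performance-curve fitting (Gaussian,
  Sharpe–Schoolfield); the construction here is deliberately piecewise
  linear. An exponential rise option exists in the generator for
  sensitivity tests, not in the fitting stage.
* No absolute qPCR quantification, primer design or melting-curve QC.
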