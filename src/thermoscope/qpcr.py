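"""Relative RT-qPCR quantification: RQ -> NF -> NRQ -> CNRQ.

Implements the multi-reference-gene relative quantification chain used for
heat-shock gene expression work:

* technical replicates of each sample x gene are averaged on the Cq scale;
* relative quantities RQ = E^(Cq_mean_gene - Cq) scale each sample against
  the gene's run average with gene-specific amplification efficiency E;
* a per-sample normalization factor NF is the geometric mean of the
  reference-gene RQs; NRQ = RQ_target / NF;
* CNRQ rescales NRQ by the geometric mean over a calibration set (default:
  every sample in the run, so CNRQ has geometric mean 1 across the run).

Also provides the geNorm reference-stability measure M (mean sd of pairwise
log2 expression ratios; lower is more stable, with < 0.5 the customary
homogeneity threshold), log-symmetric confidence intervals for group
geometric means, and a Mann-Whitney comparison that is exact for small
groups.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, ThermoscopeError

CQ_COLUMNS = ("sample_id", "group", "gene", "replicate", "cq")

HIGH_REPLICATE_SD = "HIGH_REPLICATE_SD"
N_EQ_1 = "N_EQ_1"

STABILITY_M_THRESHOLD = 0.5


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def read_cq_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: Cq file is empty")
    _require_columns(df, CQ_COLUMNS, str(path))
    if not np.all(np.isfinite(df["cq"])) or np.any(df["cq"] <= 0):
        raise SchemaError(f"{path}: Cq values must be finite and positive")
    return df


def collapse_replicates(table: pd.DataFrame, sd_warn: float = 0.5) -> pd.DataFrame:
    """Mean Cq per sample x gene; noisy replicate sets are flagged, not dropped.

    Returns columns sample_id, group, gene, cq, cq_sd, n_replicates, flags.
    A replicate sd above ``sd_warn`` cycles yields HIGH_REPLICATE_SD; a
    single replicate yields N_EQ_1.
    """
    _require_columns(table, CQ_COLUMNS, "Cq table")
    agg = (
        table.groupby(["sample_id", "group", "gene"], sort=True)["cq"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    agg = agg.rename(columns={"mean": "cq", "std": "cq_sd", "count": "n_replicates"})
    agg["cq_sd"] = agg["cq_sd"].fillna(0.0)
    flags = []
    for row in agg.itertuples():
        f = []
        if row.n_replicates == 1:
            f.append(N_EQ_1)
        if row.cq_sd > sd_warn:
            f.append(HIGH_REPLICATE_SD)
        flags.append(";".join(f))
    agg["flags"] = flags
    return agg


def efficiency_from_standard_curve(
    dilution_log10: Sequence[float], cq: Sequence[float]
) -> float:
    """Amplification efficiency E = 10^(-1/slope) from a dilution series."""
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(cq, dtype=float)
    if len(x) < 3:
        raise ThermoscopeError("standard curve needs at least 3 dilution points")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ThermoscopeError(
            "standard-curve slope must be negative (Cq falls with template)"
        )
    return float(10.0 ** (-1.0 / res.slope))


def _efficiency_for(gene: str, efficiencies) -> float:
    if efficiencies is None:
        return 2.0
    if isinstance(efficiencies, Mapping):
        e = float(efficiencies.get(gene, 2.0))
    else:
        e = float(efficiencies)
    if not (1.0 < e <= 2.2):
        raise ThermoscopeError(f"efficiency for {gene} outside (1, 2.2]: {e}")
    return e


def relative_quantities(
    mean_cq: pd.DataFrame,
    efficiencies: Mapping[str, float] | float | None = None,
) -> pd.DataFrame:
    """RQ per sample x gene: RQ = E^(Cq_bar - Cq) with Cq_bar the gene's run mean.

    ``efficiencies`` maps gene -> E; a scalar applies to every gene and the
    default (2.0) assumes perfect doubling per cycle.
    """
    _require_columns(mean_cq, ("sample_id", "group", "gene", "cq"), "mean-Cq table")
    out = mean_cq.reset_index(drop=True).copy()
    rq = np.empty(len(out))
    for gene, grp in out.groupby("gene"):
        e = _efficiency_for(gene, efficiencies)
        cq_bar = grp["cq"].mean()
        rq[grp.index.to_numpy()] = e ** (cq_bar - grp["cq"].to_numpy())
    out["rq"] = rq
    return out


def _gmean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def cnrq(
    rq_table: pd.DataFrame,
    reference_genes: Sequence[str],
    target_genes: Sequence[str] | None = None,
    calibration: str = "all_samples",
) -> pd.DataFrame:
    """Calibrated normalized relative quantities per sample x target gene.

    NF_i = geometric mean of the reference-gene RQs of sample i;
    NRQ_i = RQ_target,i / NF_i; CNRQ_i = NRQ_i / G with G the geometric
    mean of NRQ over the calibration set — all samples by default, or the
    samples of one group when ``calibration`` names a group label.
    Calibration only rescales: CNRQ ratios between samples never depend on
    it.
    """
    _require_columns(rq_table, ("sample_id", "group", "gene", "rq"), "RQ table")
    if np.any(rq_table["rq"] <= 0):
        raise ThermoscopeError("non-positive RQ: corrupt input upstream")
    reference_genes = list(reference_genes)
    if len(reference_genes) < 2:
        raise ThermoscopeError("need at least 2 reference genes for normalization")
    wide = rq_table.pivot_table(index="sample_id", columns="gene", values="rq")
    missing_refs = [g for g in reference_genes if g not in wide.columns]
    if missing_refs:
        raise ThermoscopeError(f"reference gene(s) missing from table: {missing_refs}")
    if wide[reference_genes].isna().any().any():
        raise ThermoscopeError("some samples lack a reference-gene measurement")
    groups = rq_table.groupby("sample_id")["group"].first()
    if target_genes is None:
        target_genes = [g for g in wide.columns if g not in reference_genes]
    nf = np.exp(np.log(wide[reference_genes]).mean(axis=1))
    rows = []
    for gene in target_genes:
        if gene not in wide.columns:
            raise ThermoscopeError(f"target gene missing from table: {gene}")
        nrq = wide[gene] / nf
        if calibration == "all_samples":
            cal = nrq.dropna()
        else:
            cal_samples = groups[groups == calibration].index
            if len(cal_samples) == 0:
                raise ThermoscopeError(f"calibration group not found: {calibration}")
            cal = nrq.loc[cal_samples].dropna()
        g = _gmean(cal.to_numpy())
        for sample_id, value in nrq.dropna().items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": groups[sample_id],
                    "gene": gene,
                    "nf": float(nf[sample_id]),
                    "nrq": float(value),
                    "cnrq": float(value / g),
                }
            )
    return pd.DataFrame(rows)


def genorm_m(rq_table: pd.DataFrame, genes: Sequence[str] | None = None) -> pd.Series:
    """geNorm expression-stability M per candidate reference gene.

    For genes j, k the pairwise variation V_jk is the sample standard
    deviation (n-1) of log2(RQ_j/RQ_k) across samples; M_j is the mean of
    V_jk over all k != j. Rescaling any gene's RQ by a constant leaves M
    unchanged.
    """
    _require_columns(rq_table, ("sample_id", "gene", "rq"), "RQ table")
    wide = rq_table.pivot_table(index="sample_id", columns="gene", values="rq")
    if genes is not None:
        wide = wide[list(genes)]
    wide = wide.dropna()
    if wide.shape[1] < 2:
        raise ThermoscopeError("geNorm needs at least 2 candidate genes")
    if wide.shape[0] < 2:
        raise ThermoscopeError("geNorm needs at least 2 samples")
    logs = np.log2(wide.to_numpy())
    cols = list(wide.columns)
    m = {}
    for j, gj in enumerate(cols):
        v = [
            np.std(logs[:, j] - logs[:, k], ddof=1)
            for k in range(len(cols))
            if k != j
        ]
        m[gj] = float(np.mean(v))
    return pd.Series(m, name="M")


def group_summary(
    cnrq_table: pd.DataFrame, confidence: float = 0.95
) -> pd.DataFrame:
    """Geometric mean CNRQ with a log-symmetric CI per group x gene.

    The CI is a t interval on log2(CNRQ), back-transformed, so
    ci_high / geo_mean == geo_mean / ci_low. Groups of one sample report
    the point estimate with an N_EQ_1 flag and no interval.
    """
    _require_columns(cnrq_table, ("group", "gene", "cnrq"), "CNRQ table")
    rows = []
    for (group, gene), grp in cnrq_table.groupby(["group", "gene"], sort=True):
        y = np.log2(grp["cnrq"].to_numpy())
        n = len(y)
        geo = float(2.0 ** np.mean(y))
        if n < 2:
            rows.append(
                {
                    "group": group,
                    "gene": gene,
                    "n": n,
                    "geo_mean": geo,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "flags": N_EQ_1,
                }
            )
            continue
        half = stats.t.ppf((1 + confidence) / 2, n - 1) * np.std(y, ddof=1) / np.sqrt(n)
        rows.append(
            {
                "group": group,
                "gene": gene,
                "n": n,
                "geo_mean": geo,
                "ci_low": float(2.0 ** (np.mean(y) - half)),
                "ci_high": float(2.0 ** (np.mean(y) + half)),
                "flags": "",
            }
        )
    return pd.DataFrame(rows)


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is the statistic of ``group_a``.

    ``mode='auto'`` uses the exact null distribution when the smaller group
    has <= 10 observations and the data are tie-free, falling back to the
    normal approximation with tie and continuity corrections otherwise;
    ``mode='exact'`` forces the exact distribution. Two identical samples
    return p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ThermoscopeError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "exact" or (mode == "auto" and min(len(a), len(b)) <= 10 and not has_ties):
        method = "exact"
    elif mode in ("auto", "approx"):
        method = "asymptotic"
    else:
        raise ThermoscopeError(f"unknown mode: {mode}")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    cnrq_table: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]],
    mode: str = "auto",
) -> pd.DataFrame:
    """Mann-Whitney comparison of CNRQ between group pairs, per target gene."""
    rows = []
    for gene, gene_tab in cnrq_table.groupby("gene"):
        for ga, gb in comparisons:
            a = gene_tab.loc[gene_tab["group"] == ga, "cnrq"].to_numpy()
            b = gene_tab.loc[gene_tab["group"] == gb, "cnrq"].to_numpy()
            if len(a) == 0 or len(b) == 0:
                raise ThermoscopeError(f"comparison {ga} vs {gb}: empty group for {gene}")
            u, p = mann_whitney(a, b, mode=mode)
            rows.append(
                {
                    "gene": gene,
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": len(a),
                    "n_b": len(b),
                    "U": u,
                    "p_value": p,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


def pool_groups(table: pd.DataFrame, pooling: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Relabel groups so that several source groups pool into one label."""
    mapping = {}
    for pooled, members in pooling.items():
        for m in members:
            mapping[m] = pooled
    out = table.copy()
    out["group"] = out["group"].map(lambda g: mapping.get(g, g))
    return out


def analyze_cq_table(
    cq: pd.DataFrame,
    reference_genes: Sequence[str],
    target_genes: Sequence[str] | None = None,
    *,
    efficiencies: Mapping[str, float] | float | None = None,
    calibration: str = "all_samples",
    comparisons: Sequence[tuple[str, str]] | None = None,
    pooling: Mapping[str, Sequence[str]] | None = None,
    sd_warn: float = 0.5,
) -> dict:
    """One-stop qPCR analysis: replicate collapse through group comparisons.

    Returns a dict with keys ``mean_cq``, ``rq``, ``cnrq``, ``genorm``
    (gene, M, stable), ``summary`` and, when ``comparisons`` is given,
    ``comparisons``.
    """
    if pooling:
        cq = pool_groups(cq, pooling)
    mean_cq = collapse_replicates(cq, sd_warn=sd_warn)
    rq = relative_quantities(mean_cq, efficiencies)
    cnrq_table = cnrq(rq, reference_genes, target_genes, calibration)
    ref_rq = rq[rq["gene"].isin(reference_genes)]
    m = genorm_m(ref_rq, reference_genes)
    genorm = pd.DataFrame(
        {
            "gene": m.index,
            "M": m.to_numpy(),
            "stable": m.to_numpy() < STABILITY_M_THRESHOLD,
        }
    )
    out = {
        "mean_cq": mean_cq,
        "rq": rq,
        "cnrq": cnrq_table,
        "genorm": genorm,
        "summary": group_summary(cnrq_table),
    }
    if comparisons:
        out["comparisons"] = compare_groups(cnrq_table, comparisons)
    return out
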