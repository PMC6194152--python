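"""Differential-expression screening and quality filtering.

The screen follows the classic microarray recipe: an empirical-Bayes
moderated t-test per gene for each (reference vs. test-condition) contrast,
a fold-change + FDR pass rule, intersection of the two contrasts, probe →
gene collapsing by the MaxMean rule, removal of outlying samples by
standardised sample-network connectivity, and an iterative good-samples/
good-genes filter.

The moderated t shrinks each gene's residual variance toward a pooled prior:
with per-gene residual variance s_g^2 on d_g degrees of freedom and a prior
(d0, s0^2) estimated by method of moments on log s_g^2 across genes, the
posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and t_g = logFC_g / (s~_g * sqrt(1/nA + 1/nB)) is referred to a t
distribution on d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionDataset, InputError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Thresholds of the screening pipeline (linear-scale FC, BH FDR)."""

    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    outlier_z_cut: float = -2.5
    max_missing_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise InputError("fc_threshold must be >= 1 (linear scale)")
        if not (0 < self.fdr_threshold <= 1):
            raise InputError("fdr_threshold must be in (0, 1]")
        if not (0 <= self.max_missing_fraction < 1):
            raise InputError("max_missing_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior (method of moments on log variances)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Matches log s_g^2 moments against the log-F distribution implied by the
    hierarchical model.  A non-positive moment estimate of the prior df
    yields d0 = inf (full shrinkage to the common value), logged.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        logger.warning("non-positive prior-df moment estimate; using d0 = inf")
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    data: ExpressionDataset,
    group_a: str,
    group_b: str,
    config: PreprocessConfig | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test between two condition groups.

    Returns a DataFrame with columns ``log2_fc`` (mean of ``group_b`` minus
    mean of ``group_a``), ``t``, ``p_value``, ``fdr`` and ``pass`` (the FC &
    FDR rule of ``config``).  ``prior_df`` overrides the estimated d0
    (``0`` gives the ordinary pooled-variance t; ``inf`` full shrinkage).
    """
    config = config or PreprocessConfig()
    A = data.condition(group_a).to_numpy(dtype=float)
    B = data.condition(group_b).to_numpy(dtype=float)
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a < 2 or n_b < 2:
        raise InputError(
            f"insufficient replication: {group_a} has {n_a}, {group_b} has {n_b} "
            "samples (need >= 2 each)"
        )
    df_resid = n_a + n_b - 2
    log_fc = B.mean(axis=1) - A.mean(axis=1)
    ss = A.var(axis=1, ddof=1) * (n_a - 1) + B.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    stderr = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    t = np.zeros_like(log_fc)
    nonzero = stderr > 0
    t[nonzero] = log_fc[nonzero] / stderr[nonzero]
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    # degenerate: no residual information anywhere -> uninformative
    p[~nonzero] = 1.0

    fdr = bh_fdr(p)
    passes = (np.abs(log_fc) >= np.log2(config.fc_threshold)) & (
        fdr < config.fdr_threshold
    )
    return pd.DataFrame(
        {"log2_fc": log_fc, "t": t, "p_value": p, "fdr": fdr, "pass": passes},
        index=data.genes,
    )


def select_common_degs(
    result_a: pd.DataFrame, result_b: pd.DataFrame, config: PreprocessConfig | None = None
) -> pd.Index:
    """Rows passing the FC & FDR rule in BOTH contrasts."""
    config = config or PreprocessConfig()
    if set(result_a.index) != set(result_b.index):
        raise InputError("contrast results computed on different row universes")
    result_b = result_b.loc[result_a.index]

    def _passes(res: pd.DataFrame) -> pd.Series:
        return (res["log2_fc"].abs() >= np.log2(config.fc_threshold)) & (
            res["fdr"] < config.fdr_threshold
        )

    both = _passes(result_a) & _passes(result_b)
    return result_a.index[both]


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes(data: ExpressionDataset, probe_map: pd.DataFrame) -> ExpressionDataset:
    """Collapse probes to gene symbols by the MaxMean rule.

    ``probe_map`` has columns (probe_id, gene_symbol), one row per mapping.
    Probes mapping to more than one distinct gene are discarded; among the
    probes of one gene, the probe with the highest mean expression across all
    samples represents the gene.
    """
    if probe_map is None or len(probe_map) == 0:
        raise InputError("probe map is empty")
    pm = probe_map.iloc[:, :2].copy()
    pm.columns = ["probe_id", "gene_symbol"]
    pm = pm.drop_duplicates()
    multi = pm.groupby("probe_id")["gene_symbol"].nunique()
    ambiguous = set(multi.index[multi > 1])
    pm = pm[~pm["probe_id"].isin(ambiguous)]
    pm = pm[pm["probe_id"].isin(data.genes)]
    if len(pm) == 0:
        raise InputError("no probe of the expression matrix maps uniquely to a gene")

    means = data.expr.mean(axis=1)
    rows: dict[str, str] = {}
    for gene, grp in pm.groupby("gene_symbol"):
        probes = grp["probe_id"].tolist()
        rows[gene] = max(probes, key=lambda p: (means[p], p))
    genes = sorted(rows)
    collapsed = data.expr.loc[[rows[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="gene")
    return ExpressionDataset(collapsed, data.conditions)


# ---------------------------------------------------------------------------
# sample-network outlier detection
# ---------------------------------------------------------------------------

def standardized_sample_connectivity(data: ExpressionDataset) -> pd.Series:
    """Z.k per sample from the distance-based sample network.

    Samples are nodes; adjacency A_uv = 1 - (d_uv / max d)^2 from Euclidean
    distances between expression profiles; connectivity k_u = sum_v A_uv;
    Z.k standardises k across samples.
    """
    X = data.expr.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 4:
        raise InputError("need >= 4 samples for outlier detection")
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(X, metric="euclidean"))
    dmax = D.max()
    if dmax == 0:
        logger.warning("all samples identical; no outliers detectable")
        return pd.Series(np.zeros(X.shape[0]), index=data.samples)
    A = 1.0 - (D / dmax) ** 2
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    sd = k.std(ddof=1)
    if sd == 0:
        logger.warning("sample connectivity has zero spread; no outliers flagged")
        return pd.Series(np.zeros_like(k), index=data.samples)
    return pd.Series((k - k.mean()) / sd, index=data.samples)


def detect_outlier_samples(data: ExpressionDataset, z_cut: float = -2.5) -> list:
    """Samples whose standardised connectivity Z.k falls below ``z_cut``."""
    zk = standardized_sample_connectivity(data)
    return list(zk.index[zk < z_cut])


# ---------------------------------------------------------------------------
# good samples / good genes
# ---------------------------------------------------------------------------

def filter_good_samples_genes(
    data: ExpressionDataset, max_missing_fraction: float = 0.5
) -> ExpressionDataset:
    """Iteratively drop high-missingness genes/samples and zero-variance genes."""
    expr = data.expr.copy()
    last_axis = None
    changed = True
    while changed:
        changed = False
        if expr.shape[1]:
            frac = expr.isna().mean(axis=1)
            bad_genes = frac.index[frac > max_missing_fraction]
            if len(bad_genes):
                expr = expr.drop(index=bad_genes)
                last_axis, changed = "genes", True
        if expr.shape[0]:
            var = expr.var(axis=1, skipna=True)
            const = var.index[(var == 0) | var.isna()]
            if len(const):
                expr = expr.drop(index=const)
                last_axis, changed = "genes", True
        if expr.shape[0]:
            frac = expr.isna().mean(axis=0)
            bad_samples = frac.index[frac > max_missing_fraction]
            if len(bad_samples):
                expr = expr.drop(columns=bad_samples)
                last_axis, changed = "samples", True
        if expr.size == 0:
            raise InputError(f"filtering removed everything (last removed: {last_axis})")
    return ExpressionDataset(expr, data.conditions.loc[expr.columns])


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------

def preprocess_pipeline(
    data: ExpressionDataset,
    config: PreprocessConfig | None = None,
    probe_map: pd.DataFrame | None = None,
    reference: str = "REF",
    tests: tuple[str, str] = ("TEST1", "TEST2"),
) -> tuple[ExpressionDataset, dict]:
    """DEG screen → intersect contrasts → collapse → outliers → good-genes.

    Returns the filtered dataset and an audit dict recording what each stage
    removed and why.
    """
    config = config or PreprocessConfig()
    audit: dict = {"order": [
        "deg_screen", "intersect_contrasts", "collapse_probes",
        "outlier_samples", "good_samples_genes",
    ]}
    res_a = moderated_t_test(data, reference, tests[0], config)
    res_b = moderated_t_test(data, reference, tests[1], config)
    audit["degs_contrast1"] = int(res_a["pass"].sum())
    audit["degs_contrast2"] = int(res_b["pass"].sum())
    common = select_common_degs(res_a, res_b, config)
    audit["common_degs"] = len(common)
    data = data.subset_genes(common)

    if probe_map is not None:
        before = data.expr.shape[0]
        data = collapse_probes(data, probe_map)
        audit["probes_collapsed_to_genes"] = {"probes": before, "genes": data.expr.shape[0]}

    outliers = detect_outlier_samples(data, config.outlier_z_cut)
    audit["outlier_samples_removed"] = list(outliers)
    if outliers:
        data = data.drop_samples(outliers)

    before_shape = data.expr.shape
    data = filter_good_samples_genes(data, config.max_missing_fraction)
    audit["good_filter"] = {"before": list(before_shape), "after": list(data.expr.shape)}
    return data, audit
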