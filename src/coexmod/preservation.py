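"""Permutation-based module preservation between conditions.

Modules are defined on the reference condition; preservation asks whether a
module's density (how tightly its genes stay connected) and connectivity
pattern (whether the same genes stay central) recur in a test condition.

Seven observed statistics are computed per (module, test condition):

density, on the test data only
    1. mean within-module signed adjacency
    2. mean within-module correlation
    3. proportion of variance explained by the module eigengene
    4. mean signed module membership (kME)

connectivity, comparing reference and test
    5. correlation of intramodular connectivity vectors (cor.kIM)
    6. correlation of kME vectors (cor.kME)
    7. correlation of the vectorised within-module correlation matrices

Each statistic is standardised against a permutation null in which module
labels are randomly reassigned to genes of the test data (module sizes
preserved; grey genes participate in the pool).  Zdensity and Zconnectivity
are the medians of their groups' Z scores, Zsummary their mean.  medianRank
is the median, across the seven *observed* statistics, of the module's rank
(rank 1 = strongest preservation); it involves no permutations and is
insensitive to module size.  A module is called non-preserved when
Zsummary < 5 or medianRank >= 8 (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .containers import GREY, InputError, ModulePartition
from .correlation import bicor, correlation_matrix

logger = logging.getLogger(__name__)

DENSITY_STATS = ("mean_adj", "mean_cor", "prop_var_explained", "mean_signed_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


@dataclass
class PreservationConfig:
    """Permutation-test settings (200 permutations, Z < 5 / rank >= 8 rule)."""

    n_permutations: int = 200
    z_threshold: float = 5.0
    rank_threshold: float = 8.0
    power: float = 13.0
    correlation_kind: str = "bicor"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 20:
            raise InputError("n_permutations must be >= 20")


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _eigengene(X: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC (unit norm, sign-aligned to the mean profile) + var explained."""
    Xs = _standardize_rows(X)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    e = Vt[0]
    if np.dot(e, Xs.mean(axis=0)) < 0:
        e = -e
    tot = (S**2).sum()
    return e / np.linalg.norm(e), float(S[0] ** 2 / tot) if tot > 0 else 0.0


def _pearson_vec(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _geneset_statistics(
    idx: np.ndarray,
    R_ref: np.ndarray,
    R_test: np.ndarray,
    X_ref: np.ndarray,
    X_test: np.ndarray,
    power: float,
    correlation_kind: str,
) -> dict:
    """The seven preservation statistics for one gene index set."""
    Rr = R_ref[np.ix_(idx, idx)]
    Rt = R_test[np.ix_(idx, idx)]
    m = idx.size
    triu = np.triu_indices(m, k=1)

    A_r = ((1.0 + Rr) / 2.0) ** power
    A_t = ((1.0 + Rt) / 2.0) ** power

    e_t, var_exp = _eigengene(X_test[idx])
    e_r, _ = _eigengene(X_ref[idx])
    kme_t = correlation_matrix(X_test[idx], Y=e_t[None, :], kind=correlation_kind)[:, 0]
    kme_r = correlation_matrix(X_ref[idx], Y=e_r[None, :], kind=correlation_kind)[:, 0]

    kim_r = A_r.sum(axis=1) - 1.0
    kim_t = A_t.sum(axis=1) - 1.0

    return {
        "mean_adj": float(A_t[triu].mean()),
        "mean_cor": float(Rt[triu].mean()),
        "prop_var_explained": var_exp,
        "mean_signed_kme": float(kme_t.mean()),
        "cor_kim": _pearson_vec(kim_r, kim_t),
        "cor_kme": _pearson_vec(kme_r, kme_t),
        "cor_cor": _pearson_vec(Rr[triu], Rt[triu]),
    }


class _PreservationWorkspace:
    """Precomputed correlation matrices shared by observed and null passes.

    Relabelling genes does not change the correlation matrix, so the ref and
    test matrices are computed once and every (observed or permuted) module
    statistic is a submatrix computation.
    """

    def __init__(self, ref_expr: pd.DataFrame, test_expr: pd.DataFrame,
                 power: float, correlation_kind: str):
        if list(ref_expr.index) != list(test_expr.index):
            missing = [g for g in ref_expr.index if g not in set(test_expr.index)]
            if missing:
                raise InputError(f"genes missing from test matrix: {missing[:10]}")
            test_expr = test_expr.loc[ref_expr.index]
        self.genes = ref_expr.index
        self.X_ref = ref_expr.to_numpy(dtype=float)
        self.X_test = test_expr.to_numpy(dtype=float)
        self.R_ref = correlation_matrix(self.X_ref, kind=correlation_kind)
        self.R_test = correlation_matrix(self.X_test, kind=correlation_kind)
        self.power = power
        self.correlation_kind = correlation_kind

    def stats(self, idx: np.ndarray) -> dict:
        return _geneset_statistics(
            idx, self.R_ref, self.R_test, self.X_ref, self.X_test,
            self.power, self.correlation_kind,
        )


def _module_indices(genes: pd.Index, partition: ModulePartition) -> dict[str, np.ndarray]:
    pos = {g: i for i, g in enumerate(genes)}
    out: dict[str, np.ndarray] = {}
    for module in partition.module_names:
        mg = partition.genes_of(module)
        missing = [g for g in mg if g not in pos]
        if missing:
            raise InputError(
                f"module {module}: genes missing from expression matrix: {missing[:10]}"
            )
        if len(mg) < 2:
            raise InputError(f"module {module} has fewer than 2 genes")
        out[module] = np.array([pos[g] for g in mg], dtype=int)
    return out


def observed_statistics(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    partition: ModulePartition,
    power: float = 13.0,
    correlation_kind: str = "bicor",
) -> pd.DataFrame:
    """Observed preservation statistics per non-grey module (rows) × statistic."""
    ws = _PreservationWorkspace(ref_expr, test_expr, power, correlation_kind)
    idx = _module_indices(ws.genes, partition)
    rows = {m: ws.stats(i) for m, i in idx.items()}
    return pd.DataFrame(rows).T.loc[:, list(ALL_STATS)]


def permutation_null(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    partition: ModulePartition,
    n_permutations: int = 200,
    seed: int = 0,
    power: float = 13.0,
    correlation_kind: str = "bicor",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Null mean and sd per (module, statistic) from random relabellings.

    Each permutation reassigns module labels to genes drawn (without
    replacement, disjointly across modules) from the full gene universe of
    the test data, grey genes included.  Deterministic given ``seed``.
    """
    if n_permutations < 20:
        raise InputError("n_permutations must be >= 20")
    ws = _PreservationWorkspace(ref_expr, test_expr, power, correlation_kind)
    idx = _module_indices(ws.genes, partition)
    rng = np.random.default_rng(seed)
    n_genes = len(ws.genes)
    acc: dict[str, list[dict]] = {m: [] for m in idx}
    for _ in range(n_permutations):
        perm = rng.permutation(n_genes)
        start = 0
        for module, members in idx.items():
            size = members.size
            acc[module].append(ws.stats(np.sort(perm[start : start + size])))
            start += size
    means = pd.DataFrame(
        {m: pd.DataFrame(v).mean() for m, v in acc.items()}
    ).T.loc[:, list(ALL_STATS)]
    sds = pd.DataFrame(
        {m: pd.DataFrame(v).std(ddof=1) for m, v in acc.items()}
    ).T.loc[:, list(ALL_STATS)]
    return means, sds


def zsummary_medianrank(
    observed: pd.DataFrame, null_mean: pd.DataFrame, null_sd: pd.DataFrame
) -> pd.DataFrame:
    """Combine observed and null tables into the composite statistics.

    Returns a DataFrame indexed by module with per-statistic Z scores plus
    ``Zdensity`` (median of density Zs), ``Zconnectivity`` (median of
    connectivity Zs), ``Zsummary`` (their mean) and ``medianRank`` (median of
    the module's ranks across the seven observed statistics; rank 1 =
    strongest preservation).
    """
    if not observed.index.equals(null_mean.index) or not observed.index.equals(
        null_sd.index
    ):
        raise InputError("observed and null tables cover different modules")
    Z = pd.DataFrame(index=observed.index, columns=[f"Z_{s}" for s in ALL_STATS],
                     dtype=float)
    for s in ALL_STATS:
        sd = null_sd[s].to_numpy(dtype=float)
        num = observed[s].to_numpy(dtype=float) - null_mean[s].to_numpy(dtype=float)
        z = np.zeros_like(num)
        ok = sd > 0
        if not ok.all():
            logger.warning("zero permutation sd for statistic %s; Z set to 0", s)
        z[ok] = num[ok] / sd[ok]
        Z[f"Z_{s}"] = z
    out = Z.copy()
    out["Zdensity"] = Z[[f"Z_{s}" for s in DENSITY_STATS]].median(axis=1)
    out["Zconnectivity"] = Z[[f"Z_{s}" for s in CONNECTIVITY_STATS]].median(axis=1)
    out["Zsummary"] = (out["Zdensity"] + out["Zconnectivity"]) / 2.0
    ranks = pd.DataFrame(index=observed.index, dtype=float)
    for s in ALL_STATS:
        ranks[s] = rankdata(-observed[s].to_numpy(dtype=float), method="average")
    out["medianRank"] = ranks.median(axis=1)
    return out


def classify_preservation(
    stats: pd.DataFrame, z_threshold: float = 5.0, rank_threshold: float = 8.0
) -> pd.Series:
    """'non-preserved' iff Zsummary < z_threshold OR medianRank >= rank_threshold."""
    non = (stats["Zsummary"] < z_threshold) | (stats["medianRank"] >= rank_threshold)
    return pd.Series(
        np.where(non, "non-preserved", "preserved"), index=stats.index, name="call"
    )


def preservation_report(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    partition: ModulePartition,
    config: PreservationConfig | None = None,
) -> pd.DataFrame:
    """Full preservation analysis of one test condition against the reference."""
    config = config or PreservationConfig()
    obs = observed_statistics(
        ref_expr, test_expr, partition, config.power, config.correlation_kind
    )
    null_mean, null_sd = permutation_null(
        ref_expr,
        test_expr,
        partition,
        config.n_permutations,
        config.seed,
        config.power,
        config.correlation_kind,
    )
    stats = zsummary_medianrank(obs, null_mean, null_sd)
    report = obs.join(stats)
    report["call"] = classify_preservation(
        stats, config.z_threshold, config.rank_threshold
    )
    return report


def global_concordance(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    power: float = 13.0,
    correlation_kind: str = "bicor",
) -> tuple[float, float]:
    """(expression correlation, connectivity correlation) between conditions.

    Correlates per-gene mean expression across conditions and per-gene
    whole-network connectivity k across conditions — the diagnostic contrast
    between conserved expression and disrupted wiring.
    """
    if list(ref_expr.index) != list(test_expr.index):
        test_expr = test_expr.loc[ref_expr.index]
    mean_r = ref_expr.mean(axis=1).to_numpy(dtype=float)
    mean_t = test_expr.mean(axis=1).to_numpy(dtype=float)
    expr_cor = bicor(mean_r, mean_t)

    def _k(X: pd.DataFrame) -> np.ndarray:
        R = correlation_matrix(X.to_numpy(dtype=float), kind=correlation_kind)
        A = ((1.0 + R) / 2.0) ** power
        np.fill_diagonal(A, 1.0)
        return A.sum(axis=1) - 1.0

    k_cor = bicor(_k(ref_expr), _k(test_expr))
    return float(expr_cor), float(k_cor)


class ModulePreservation(BaseEstimator):
    """Estimator wrapper around the permutation preservation test.

    ``fit(X_ref, X_test, labels)`` runs the analysis; fitted attributes are
    ``stats_`` (per-module statistics, Zs, medianRank) and ``calls_``
    (preserved / non-preserved per module).
    """

    def __init__(
        self,
        n_permutations: int = 200,
        z_threshold: float = 5.0,
        rank_threshold: float = 8.0,
        power: float = 13.0,
        correlation_kind: str = "bicor",
        seed: int = 0,
    ):
        self.n_permutations = n_permutations
        self.z_threshold = z_threshold
        self.rank_threshold = rank_threshold
        self.power = power
        self.correlation_kind = correlation_kind
        self.seed = seed

    def fit(self, X_ref: pd.DataFrame, X_test: pd.DataFrame, labels):
        if isinstance(labels, ModulePartition):
            partition = labels
        else:
            partition = ModulePartition(pd.Series(labels, index=X_ref.index))
        config = PreservationConfig(
            n_permutations=self.n_permutations,
            z_threshold=self.z_threshold,
            rank_threshold=self.rank_threshold,
            power=self.power,
            correlation_kind=self.correlation_kind,
            seed=self.seed,
        )
        report = preservation_report(X_ref, X_test, partition, config)
        self.stats_ = report
        self.calls_ = report["call"]
        return self
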