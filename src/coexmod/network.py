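"""Signed weighted co-expression network construction and module detection.

The network is built on the reference condition only: pairwise biweight
midcorrelations r_ij are mapped to a signed adjacency

    a_ij = ((1 + r_ij) / 2) ** beta,

so anticorrelated genes disconnect (r = -1 -> a = 0) while uncorrelated pairs
fall to 2**-beta.  beta is chosen as the smallest candidate whose signed
scale-free fit index R^2 reaches the target (0.8 by default).  The adjacency
is transformed into the topological overlap matrix (TOM), genes are clustered
by average linkage on 1 - TOM, modules are cut out with a dynamic hybrid
tree-cut procedure, and modules with highly correlated eigengenes are merged
(default merge height 0.25, i.e. eigengene correlation > 0.75).

Module labels are size-ranked colour names ("turquoise" = largest); "grey"
marks unassigned genes.  Everything here is deterministic given the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from sklearn.base import BaseEstimator, ClusterMixin

from ._colors import color_label
from .containers import GREY, EigengeneSet, InputError, ModulePartition
from .correlation import correlation_matrix

logger = logging.getLogger(__name__)

#: Dynamic-cut sensitivity: core-scatter ceiling per deep-split, as a
#: fraction of the network's mean pairwise dissimilarity.
_DEEP_SPLIT_SCATTER = {0: 0.80, 1: 0.85, 2: 0.90, 3: 0.93, 4: 0.95}


@dataclass
class NetworkConfig:
    """Network construction parameters.

    ``power=None`` triggers soft-threshold selection over
    ``candidate_powers``; the study this emulates used beta = 13 chosen by
    the scale-free criterion (R^2 >= 0.8).
    """

    power: float | None = None
    r2_target: float = 0.8
    candidate_powers: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 13, 14, 16, 18, 20)
    correlation_kind: str = "bicor"
    merge_cut_height: float = 0.25
    min_module_size: int = 30
    deep_split: int = 2
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.power is not None and self.power < 1:
            raise InputError("power must be >= 1")
        if not (0 < self.merge_cut_height < 1):
            raise InputError("merge_cut_height must be in (0, 1)")
        if self.deep_split not in _DEEP_SPLIT_SCATTER:
            raise InputError("deep_split must be an integer in 0..4")


# ---------------------------------------------------------------------------
# adjacency / TOM
# ---------------------------------------------------------------------------

def signed_adjacency(R: np.ndarray, beta: float) -> np.ndarray:
    """Signed adjacency ((1 + r)/2)^beta with unit diagonal."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-10):
        raise InputError("correlation matrix must be square and symmetric")
    A = ((1.0 + R) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    A = np.asarray(adjacency, dtype=float)
    return A.sum(axis=1) - np.diag(A)


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> tuple[float, float, float]:
    """Signed scale-free fit of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins, regresses log10(frequency) on
    log10(mean k per bin) and returns (signed R^2, mean k, slope); R^2 is
    negated when the slope is positive so only decreasing degree laws score
    high.
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-12
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        raise InputError("fewer than 3 non-empty connectivity bins; fit undefined")
    fit = linregress(xs, ys)
    r2 = fit.rvalue**2
    if fit.slope > 0:
        r2 = -r2
    return float(r2), float(k.mean()), float(fit.slope)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float, float]:
    """Signed scale-free fit index of an adjacency matrix (see above)."""
    return scale_free_fit_index(connectivity(adjacency), n_bins=n_bins)


def pick_soft_threshold(
    expr,
    candidate_powers=NetworkConfig.candidate_powers,
    r2_target: float = 0.8,
    correlation_kind: str = "bicor",
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Smallest candidate power whose signed R^2 reaches the target.

    Returns (power, table of per-candidate R^2 / mean k / slope).  If no
    candidate qualifies, the argmax-R^2 candidate is returned with a warning.
    """
    candidate_powers = list(candidate_powers)
    if len(candidate_powers) < 2:
        raise InputError("need >= 2 candidate powers")
    X = np.asarray(expr, dtype=float)
    R = correlation_matrix(X, kind=correlation_kind)
    rows = []
    for beta in candidate_powers:
        try:
            r2, mean_k, slope = scale_free_fit(signed_adjacency(R, beta), n_bins=n_bins)
        except InputError:
            r2, mean_k, slope = np.nan, np.nan, np.nan
        rows.append({"power": beta, "r2": r2, "mean_k": mean_k, "slope": slope})
    table = pd.DataFrame(rows)
    ok = table["r2"] >= r2_target
    if ok.any():
        chosen = float(table.loc[ok, "power"].iloc[0])
    else:
        chosen = float(table.loc[table["r2"].idxmax(), "power"])
        logger.warning(
            "no candidate power reaches R^2 >= %.2f; using argmax power %g",
            r2_target,
            chosen,
        )
    return chosen, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a signed adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k excluding the diagonal; TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError("adjacency must be square")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise InputError("adjacency values must lie in [0, 1]")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0  # shared-neighbour sums; zero diagonal kills u = i, j terms
    k = A0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A0) / (kmin + 1.0 - A0)
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    return np.clip(T, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dynamic hybrid tree cut (two-stage approximation)
# ---------------------------------------------------------------------------

#: Fraction of the gap between core scatter and the background dissimilarity
#: level up to which members are kept / adopted around a cluster medoid.
_ADOPT_FRACTION = 0.6


def cut_tree_dynamic(
    dissimilarity: np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
    Z: np.ndarray | None = None,
) -> np.ndarray:
    """Dynamic hybrid cut of an average-linkage dendrogram.

    Two stages.  (1) Tree-based detection: every branch of at least
    ``min_module_size`` leaves is scored by its *core scatter* — the mean
    pairwise dissimilarity among the core members closest to the branch
    medoid.  A branch is a candidate when its core scatter falls below a
    deep-split-dependent fraction of the network's mean pairwise
    dissimilarity (0.90 at the default ``deep_split=2``; larger deep-split =
    more permissive = more, weaker modules).  Maximal candidates are
    selected top-down, splitting a branch whenever both of its sub-branches
    contain candidates of their own.  (2) Hybrid assignment around medoids:
    each detected cluster keeps / adopts exactly the objects whose
    dissimilarity to its medoid stays below
    ``core_scatter + 0.6 * (mean_dissimilarity - core_scatter)``; objects
    passing no cluster's threshold are unassigned.

    On structure-free (i.i.d.-noise) dissimilarities even the tightest
    branch cores sit at the mean pairwise value, so no branch qualifies and
    the genes stay unassigned.  Returns integer labels, 0 = unassigned
    (grey).
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError("dissimilarity must be square")
    n = D.shape[0]
    if n < min_module_size:
        logger.warning("fewer genes (%d) than min_module_size; all grey", n)
        return np.zeros(n, dtype=int)
    if Z is None:
        Z = linkage(squareform(D, checks=False), method="average")

    mu = float(D[np.triu_indices(n, k=1)].mean())
    rel = _DEEP_SPLIT_SCATTER[deep_split]
    max_core_scatter = rel * mu
    core_n = max(6, min_module_size // 3)

    # walk merges bottom-up, scoring every branch of admissible size
    members: list[np.ndarray] = [None] * (n - 1)  # type: ignore[list-item]
    acceptable = np.zeros(n - 1, dtype=bool)
    core_scatter = np.full(n - 1, np.inf)
    for m in range(n - 1):
        sets = []
        for child in (int(Z[m, 0]), int(Z[m, 1])):
            sets.append(np.array([child]) if child < n else members[child - n])
        mem = np.concatenate(sets)
        members[m] = mem
        if mem.size < min_module_size:
            continue
        sub = D[np.ix_(mem, mem)]
        medoid_pos = int(np.argmin(sub.sum(axis=0)))
        core = np.argsort(sub[medoid_pos])[:core_n]
        cs = float(sub[np.ix_(core, core)][np.triu_indices(core.size, k=1)].mean())
        core_scatter[m] = cs
        acceptable[m] = cs <= max_core_scatter

    # module cores = minimal acceptable branches (no acceptable descendant);
    # they are pairwise disjoint, and stage 2 settles full membership
    has_acc_subtree = acceptable.copy()
    for m in range(n - 1):
        for child in (int(Z[m, 0]), int(Z[m, 1])):
            if child >= n and has_acc_subtree[child - n]:
                has_acc_subtree[m] = True
    accepted: list[int] = []
    for m in range(n - 1):
        if not acceptable[m]:
            continue
        kids = [int(Z[m, 0]) - n, int(Z[m, 1]) - n]  # negative = leaf
        if not any(k >= 0 and has_acc_subtree[k] for k in kids):
            accepted.append(m)

    # stage 2: per-cluster medoid thresholds decide membership for everyone
    labels = np.zeros(n, dtype=int)
    if accepted:
        medoids, thresholds = [], []
        for m in accepted:
            mem = members[m]
            sub = D[np.ix_(mem, mem)]
            medoids.append(int(mem[np.argmin(sub.sum(axis=0))]))
            thresholds.append(
                core_scatter[m] + _ADOPT_FRACTION * (mu - core_scatter[m])
            )
        dist = D[:, medoids]  # n x clusters
        best = np.argmin(dist, axis=1)
        for g in range(n):
            b = int(best[g])
            if dist[g, b] <= thresholds[b]:
                labels[g] = b + 1
        for b, mo in enumerate(medoids):
            labels[mo] = b + 1
    return labels


# ---------------------------------------------------------------------------
# eigengenes and module merging
# ---------------------------------------------------------------------------

def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> EigengeneSet:
    """First principal component per module, sign-aligned, unit norm.

    ``expr`` is genes × samples; ``labels`` maps each gene to a module label.
    Modules with fewer than 2 genes are skipped with a warning.  The sign is
    flipped when the component correlates negatively with the module's mean
    standardized expression profile, so eigengenes consistently point "up"
    with their module.
    """
    scores: dict[str, np.ndarray] = {}
    var_exp: dict[str, float] = {}
    for module in [m for m in pd.unique(labels) if m != GREY]:
        genes = labels.index[labels == module]
        genes = [g for g in genes if g in expr.index]
        if len(genes) < 2:
            logger.warning("module %s has < 2 genes in the matrix; skipped", module)
            continue
        X = _standardize_rows(expr.loc[genes].to_numpy(dtype=float))
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        e = Vt[0]
        mean_profile = X.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        scores[module] = e / np.linalg.norm(e)
        var_exp[module] = float(S[0] ** 2 / (S**2).sum())
    return EigengeneSet(
        scores=pd.DataFrame(scores, index=expr.columns),
        var_explained=pd.Series(var_exp),
    )


def merge_close_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_cut_height: float = 0.25
) -> pd.Series:
    """Iteratively merge modules whose eigengene dissimilarity (1 - cor)
    stays below the merge height, until stable."""
    labels = labels.copy()
    for _ in range(20):
        eig = module_eigengenes(expr, labels)
        mods = list(eig.scores.columns)
        if len(mods) < 2:
            break
        C = np.corrcoef(eig.scores.to_numpy().T)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
        Zl = linkage(squareform(D, checks=False), method="average")
        groups = fcluster(Zl, t=merge_cut_height, criterion="distance")
        if len(np.unique(groups)) == len(mods):
            break
        sizes = labels.value_counts()
        for g in np.unique(groups):
            merged = [mods[i] for i in np.flatnonzero(groups == g)]
            if len(merged) < 2:
                continue
            target = max(merged, key=lambda m: sizes.get(m, 0))
            labels[labels.isin(merged)] = target
    return labels


def relabel_by_size(labels: pd.Series) -> pd.Series:
    """Map module labels to size-ranked colour names (grey preserved)."""
    sizes = labels[labels != GREY].value_counts()
    mapping = {m: color_label(i) for i, m in enumerate(sizes.index)}
    mapping[GREY] = GREY
    return labels.map(mapping)


# ---------------------------------------------------------------------------
# full detection pipeline + estimator
# ---------------------------------------------------------------------------

def detect_modules(
    expr: pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[ModulePartition, EigengeneSet, dict]:
    """Reference-condition module detection, end to end.

    Returns the colour-labelled partition, the eigengene set and a summary
    dict (power used, scale-free R^2, module sizes).
    """
    config = config or NetworkConfig()
    X = expr.to_numpy(dtype=float)
    R = correlation_matrix(X, kind=config.correlation_kind)
    if config.power is None:
        beta, power_table = pick_soft_threshold(
            X,
            config.candidate_powers,
            config.r2_target,
            config.correlation_kind,
            config.n_bins,
        )
    else:
        beta, power_table = float(config.power), None
    A = signed_adjacency(R, beta)
    try:
        r2, _, _ = scale_free_fit(A, n_bins=config.n_bins)
    except InputError:
        r2 = float("nan")
    T = tom_similarity(A)
    diss = 1.0 - T
    np.fill_diagonal(diss, 0.0)
    raw = cut_tree_dynamic(diss, config.min_module_size, config.deep_split)
    labels = pd.Series(
        [GREY if v == 0 else f"m{v}" for v in raw], index=expr.index, name="module"
    )
    labels = merge_close_modules(expr, labels, config.merge_cut_height)
    # dissolve modules that fell below the size floor
    sizes = labels.value_counts()
    small = [m for m in sizes.index if m != GREY and sizes[m] < config.min_module_size]
    labels[labels.isin(small)] = GREY
    labels = relabel_by_size(labels)
    partition = ModulePartition(labels)
    eig = module_eigengenes(expr, labels)
    summary = {
        "power": beta,
        "scale_free_r2": r2,
        "module_sizes": {str(k): int(v) for k, v in partition.sizes().items()},
        "n_grey": int((labels == GREY).sum()),
    }
    if power_table is not None:
        summary["power_table"] = power_table.to_dict(orient="list")
    return partition, eig, summary


class CoexpressionModules(ClusterMixin, BaseEstimator):
    """Scikit-learn-style estimator for signed co-expression module detection.

    Observations are genes (rows of X), features are samples — each gene is a
    point in sample space and clusters are co-expression modules.

    Parameters mirror :class:`NetworkConfig`.  After :meth:`fit`:

    ``labels_`` : ndarray of str, colour label per gene ("grey" = unassigned)
    ``power_`` : soft-threshold power used
    ``scale_free_r2_`` : signed scale-free fit at that power
    ``eigengenes_`` : DataFrame samples × modules
    ``var_explained_`` : Series per module
    ``partition_`` : :class:`ModulePartition`
    """

    def __init__(
        self,
        power: float | None = None,
        r2_target: float = 0.8,
        candidate_powers: tuple = NetworkConfig.candidate_powers,
        correlation_kind: str = "bicor",
        merge_cut_height: float = 0.25,
        min_module_size: int = 30,
        deep_split: int = 2,
    ):
        self.power = power
        self.r2_target = r2_target
        self.candidate_powers = candidate_powers
        self.correlation_kind = correlation_kind
        self.merge_cut_height = merge_cut_height
        self.min_module_size = min_module_size
        self.deep_split = deep_split

    def fit(self, X, y=None):
        """Detect modules on a genes × samples matrix (DataFrame or array)."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        config = NetworkConfig(
            power=self.power,
            r2_target=self.r2_target,
            candidate_powers=tuple(self.candidate_powers),
            correlation_kind=self.correlation_kind,
            merge_cut_height=self.merge_cut_height,
            min_module_size=self.min_module_size,
            deep_split=self.deep_split,
        )
        partition, eig, summary = detect_modules(X, config)
        self.partition_ = partition
        self.labels_ = partition.labels.to_numpy()
        self.eigengenes_ = eig.scores
        self.var_explained_ = eig.var_explained
        self.power_ = summary["power"]
        self.scale_free_r2_ = summary["scale_free_r2"]
        self.summary_ = summary
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
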