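"""Network construction: adjacency, scale-free fit, TOM, tree cut, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexmod import (
    CoexpressionModules,
    InputError,
    cut_tree_dynamic,
    merge_close_modules,
    module_eigengenes,
    pick_soft_threshold,
    signed_adjacency,
    tom_similarity,
)
from coexmod.network import scale_free_fit, scale_free_fit_index
from coexmod.simulate import SimulationConfig, generate_dataset


# ---------------------------------------------------------------------------
# signed adjacency
# ---------------------------------------------------------------------------

def test_signed_adjacency_endpoints():
    R = np.array([[1.0, 1.0, -1.0, 0.0],
                  [1.0, 1.0, 0.0, 0.0],
                  [-1.0, 0.0, 1.0, 0.0],
                  [0.0, 0.0, 0.0, 1.0]])
    for beta in (1, 6, 13):
        A = signed_adjacency(R, beta)
        assert A[0, 1] == pytest.approx(1.0)  # r = 1
        assert A[0, 2] == pytest.approx(0.0)  # r = -1: anticorrelated disconnect
    A13 = signed_adjacency(R, 13)
    assert A13[0, 3] == pytest.approx(2.0**-13)  # r = 0 at the study's power


def test_signed_adjacency_rejects_asymmetry():
    R = np.array([[1.0, 0.5], [0.2, 1.0]])
    with pytest.raises(InputError):
        signed_adjacency(R, 6)


# ---------------------------------------------------------------------------
# scale-free fit
# ---------------------------------------------------------------------------

def test_exact_power_law_scores_high(rng):
    # degree sequence k with frequency proportional to k^-1.5 over 10 bins
    ks = np.linspace(1, 100, 10)
    freqs = (ks**-1.5 * 3000).astype(int)
    k = np.repeat(ks, freqs) + rng.uniform(-0.2, 0.2, size=freqs.sum())
    r2, _, slope = scale_free_fit_index(k, n_bins=10)
    assert r2 >= 0.99
    assert slope < 0


def test_homogeneous_network_scores_low():
    r2s = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        # Erdos-Renyi-like: i.i.d. adjacency, narrow connectivity distribution
        A = rng.uniform(0, 0.2, size=(150, 150))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        r2, _, _ = scale_free_fit(A)
        r2s.append(r2)
    assert np.mean(r2s) < 0.5


def test_pick_soft_threshold_smallest_qualifying(default_dataset):
    data, _ = default_dataset
    expr = data.condition("REF").to_numpy()
    # degenerate target: every candidate qualifies (signed R^2 can be
    # negative, so the floor is -1, not 0) -> smallest candidate wins
    beta, table = pick_soft_threshold(expr, r2_target=-1.0)
    assert beta == table["power"].iloc[0]
    beta2, table2 = pick_soft_threshold(expr, r2_target=0.5)
    qualifying = table2.loc[table2["r2"] >= 0.5, "power"]
    assert len(qualifying) > 0 and beta2 == qualifying.iloc[0]


def test_pick_soft_threshold_needs_two_candidates(rng):
    with pytest.raises(InputError):
        pick_soft_threshold(rng.standard_normal((10, 10)), candidate_powers=[6])


# ---------------------------------------------------------------------------
# TOM
# ---------------------------------------------------------------------------

def tom_oracle(A):
    """Triple-loop transcription of the topological overlap formula."""
    n = A.shape[0]
    k = A.sum(axis=1) - np.diag(A)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def test_tom_trivial_cases():
    A = np.array([[1.0, 1.0], [1.0, 1.0]])
    assert tom_similarity(A)[0, 1] == pytest.approx(1.0)  # isolated perfect pair
    A = np.eye(5)
    T = tom_similarity(A)
    assert np.allclose(T - np.eye(5), 0.0)  # no edges -> no overlap


def test_tom_matches_brute_force(rng):
    for _ in range(300):
        n = int(rng.integers(4, 9))
        A = rng.uniform(size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        assert np.allclose(tom_similarity(A), tom_oracle(A), atol=1e-12)


def test_tom_rejects_out_of_range():
    A = np.full((3, 3), 1.5)
    with pytest.raises(InputError):
        tom_similarity(A)


# ---------------------------------------------------------------------------
# dynamic tree cut
# ---------------------------------------------------------------------------

def planted_block_dissimilarity(rng, n_blocks=4, size=40, within=0.1, between=0.9):
    n = n_blocks * size
    D = np.full((n, n), between)
    for b in range(n_blocks):
        sl = slice(b * size, (b + 1) * size)
        D[sl, sl] = within
    D += rng.uniform(-0.02, 0.02, size=(n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0, 1)


def test_planted_blocks_recovered_exactly(rng):
    D = planted_block_dissimilarity(rng)
    labels = cut_tree_dynamic(D, min_module_size=30)
    truth = np.repeat(np.arange(4), 40)
    assert (labels > 0).all()
    assert adjusted_rand_score(truth, labels) == 1.0


def test_noise_dissimilarity_mostly_grey():
    grey_fraction = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((150, 30))
        R = np.corrcoef(X)
        D = 1 - ((1 + R) / 2) ** 6
        np.fill_diagonal(D, 0.0)
        labels = cut_tree_dynamic(D, min_module_size=30)
        grey_fraction.append((labels == 0).mean())
    assert np.mean(grey_fraction) > 0.5


def test_fewer_genes_than_min_size_all_grey(rng):
    D = planted_block_dissimilarity(rng, n_blocks=1, size=10)
    labels = cut_tree_dynamic(D, min_module_size=30)
    assert (labels == 0).all()


# ---------------------------------------------------------------------------
# eigengenes and merging
# ---------------------------------------------------------------------------

def test_identical_genes_give_their_profile_back(rng):
    profile = rng.standard_normal(20)
    expr = pd.DataFrame(np.tile(profile, (5, 1)),
                        index=[f"g{i}" for i in range(5)])
    labels = pd.Series(["m1"] * 5, index=expr.index)
    eig = module_eigengenes(expr, labels)
    assert eig.var_explained["m1"] == pytest.approx(1.0)
    e = eig.scores["m1"].to_numpy()
    z = (profile - profile.mean()) / profile.std()
    assert abs(np.corrcoef(e, z)[0, 1]) == pytest.approx(1.0)
    assert np.corrcoef(e, expr.mean(axis=0))[0, 1] >= 0  # sign contract


def test_eigengene_recovers_planted_latent_factor():
    cors = []
    for seed in range(5):
        cfg = SimulationConfig(
            n_samples_per_condition=100,
            module_specs=[
                __import__("coexmod").ModuleSpec("A", 50, rho_hub=0.9)
            ],
            n_background_genes=10,
            fates={},
            seed=seed,
        )
        data, truth = generate_dataset(cfg)
        ref = data.condition("REF")
        labels = truth.module_of.loc[ref.index].replace("background", "grey")
        eig = module_eigengenes(ref, labels)
        # latent factor proxy: mean of planted hub genes
        hubs = truth.is_hub.index[truth.is_hub["REF"]]
        proxy = ref.loc[[g for g in hubs if g in ref.index]].mean(axis=0)
        cors.append(abs(np.corrcoef(eig.scores["A"], proxy)[0, 1]))
    assert min(cors) >= 0.95


def test_merge_joins_correlated_modules(rng):
    e = rng.standard_normal(40)
    X1 = 0.9 * e + np.sqrt(1 - 0.81) * rng.standard_normal((30, 40))
    X2 = 0.9 * e + np.sqrt(1 - 0.81) * rng.standard_normal((30, 40))
    expr = pd.DataFrame(np.vstack([X1, X2]),
                        index=[f"g{i}" for i in range(60)])
    labels = pd.Series(["m1"] * 30 + ["m2"] * 30, index=expr.index)
    merged = merge_close_modules(expr, labels, merge_cut_height=0.25)
    assert merged.nunique() == 1  # eigengene dissimilarity well below 0.25


def test_merge_leaves_orthogonal_modules_and_is_idempotent(rng):
    e1, e2 = rng.standard_normal((2, 60))
    X1 = 0.9 * e1 + 0.44 * rng.standard_normal((25, 60))
    X2 = 0.9 * e2 + 0.44 * rng.standard_normal((25, 60))
    expr = pd.DataFrame(np.vstack([X1, X2]),
                        index=[f"g{i}" for i in range(50)])
    labels = pd.Series(["m1"] * 25 + ["m2"] * 25, index=expr.index)
    once = merge_close_modules(expr, labels, 0.25)
    assert once.nunique() == 2
    twice = merge_close_modules(expr, once, 0.25)
    assert once.equals(twice)


# ---------------------------------------------------------------------------
# estimator end-to-end
# ---------------------------------------------------------------------------

def test_estimator_recovers_planted_partition(default_dataset):
    data, truth = default_dataset
    ref = data.condition("REF")
    det = CoexpressionModules().fit(ref)
    labels = pd.Series(det.labels_, index=ref.index)
    mask = labels != "grey"
    assert mask.sum() > 200
    truth_labels = truth.module_of.loc[ref.index]
    ari = adjusted_rand_score(truth_labels[mask], labels[mask])
    assert ari >= 0.8
    # sklearn API contracts
    params = det.get_params()
    assert params["min_module_size"] == 30
    assert det.fit_predict(ref).shape == (ref.shape[0],)


def test_detection_is_deterministic(default_dataset):
    data, _ = default_dataset
    ref = data.condition("REF")
    l1 = CoexpressionModules(power=6).fit(ref).labels_
    l2 = CoexpressionModules(power=6).fit(ref).labels_
    assert np.array_equal(l1, l2)
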