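"""Differential screen, BH-FDR, probe collapse and quality filters."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexmod import (
    ExpressionDataset,
    InputError,
    PreprocessConfig,
    bh_fdr,
    collapse_probes,
    detect_outlier_samples,
    filter_good_samples_genes,
    moderated_t_test,
    select_common_degs,
)
from .conftest import two_group_dataset


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def test_identical_groups_give_zero_statistics(rng):
    data = two_group_dataset(rng, n_genes=20)
    expr = data.expr.copy()
    expr.loc["g0", :] = 3.14  # identical in both groups
    data = ExpressionDataset(expr, data.conditions)
    res = moderated_t_test(data, "REF", "TEST1")
    assert res.loc["g0", "log2_fc"] == pytest.approx(0.0)
    assert res.loc["g0", "t"] == pytest.approx(0.0)
    assert np.isfinite(res["p_value"]).all()


def test_zero_prior_df_recovers_ordinary_pooled_t(rng):
    data = two_group_dataset(rng, n_genes=40, n_a=6, n_b=8)
    res = moderated_t_test(data, "REF", "TEST1", prior_df=0.0)
    a = data.condition("REF").to_numpy()
    b = data.condition("TEST1").to_numpy()
    t_ref, p_ref = stats.ttest_ind(b, a, axis=1, equal_var=True)
    assert np.allclose(res["t"], t_ref, atol=1e-10)
    assert np.allclose(res["p_value"], p_ref, atol=1e-10)


def test_infinite_prior_df_uses_common_variance(rng):
    data = two_group_dataset(rng, n_genes=60, n_a=5, n_b=5)
    res = moderated_t_test(data, "REF", "TEST1", prior_df=np.inf)
    # all genes shrunk to the same residual sd -> t proportional to logFC
    ratio = res["t"] / res["log2_fc"]
    assert np.allclose(ratio, ratio.iloc[0], atol=1e-9)


def test_null_pvalue_calibration():
    """2000 null genes, nA=nB=10: fraction of raw p<0.05 within [0.04, 0.06]."""
    fracs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        data = two_group_dataset(rng, n_genes=2000, n_a=10, n_b=10)
        res = moderated_t_test(data, "REF", "TEST1")
        fracs.append((res["p_value"] < 0.05).mean())
    assert 0.04 <= np.mean(fracs) <= 0.06


def test_insufficient_replication_raises(rng):
    data = two_group_dataset(rng, n_genes=10, n_a=1, n_b=5)
    with pytest.raises(InputError, match="replication"):
        moderated_t_test(data, "REF", "TEST1")


def test_agrees_with_limma_on_small_fixture(rng, tmp_path):
    """Cross-check moderated t / p against the R limma implementation."""
    data = two_group_dataset(rng, n_genes=30, n_a=5, n_b=6,
                             shift=np.linspace(-1, 1, 30))
    expr_path = tmp_path / "expr.tsv"
    data.expr.to_csv(expr_path, sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{expr_path}", row.names=1, check.names=FALSE))
        group <- factor(c(rep("A", 5), rep("B", 6)), levels=c("A","B"))
        design <- model.matrix(~group)
        fit <- eBayes(lmFit(x, design))
        out <- topTable(fit, coef=2, number=Inf, sort.by="none")
        write.table(out, "{tmp_path}/limma.tsv", sep="\t", quote=FALSE)
    """)
    r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert r.returncode == 0, r.stderr
    limma = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    res = moderated_t_test(data, "REF", "TEST1")
    assert np.allclose(res["log2_fc"], limma["logFC"], atol=1e-8)
    assert np.allclose(res["t"], limma["t"], atol=1e-4)
    assert np.allclose(res["p_value"], limma["P.Value"], atol=1e-6)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Step-up definition: p_(i) * m / i with cumulative minimum from the top."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5, 0.01], [0.5, 0.02]),
    ],
)
def test_bh_known_values(pvals, expected):
    assert np.allclose(bh_fdr(pvals), expected)


def test_bh_matches_brute_force_and_is_permutation_equivariant(rng):
    for _ in range(300):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)
    p = rng.uniform(size=25)
    perm = rng.permutation(25)
    assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))


def test_bh_rejects_out_of_range():
    with pytest.raises(InputError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# common DEGs
# ---------------------------------------------------------------------------

def _result(index, fc, fdr):
    return pd.DataFrame(
        {"log2_fc": fc, "t": 0.0, "p_value": fdr, "fdr": fdr,
         "pass": np.zeros(len(index), bool)},
        index=index,
    )


def test_common_degs_is_threshold_intersection():
    genes = list("abcdef")
    # hand-enumerated: FC >= 1.5 (|log2FC| >= 0.585) AND FDR < 0.05, both sides
    res_a = _result(genes, fc=[1.0, 0.6, 0.2, -0.9, 0.7, 0.59],
                    fdr=[0.01, 0.04, 0.01, 0.02, 0.30, 0.049])
    res_b = _result(genes, fc=[0.9, 0.1, 0.8, -0.6, 0.9, 0.60],
                    fdr=[0.02, 0.01, 0.04, 0.06, 0.01, 0.001])
    got = set(select_common_degs(res_a, res_b, PreprocessConfig()))
    # a passes both; b fails FC in B; c fails FC in A; d fails FDR in B;
    # e fails FDR in A; f passes both (0.59 and 0.60 >= log2 1.5 = 0.58496)
    assert got == {"a", "f"}


def test_common_degs_requires_same_universe():
    res_a = _result(list("abc"), [1, 1, 1], [0.01] * 3)
    res_b = _result(list("abd"), [1, 1, 1], [0.01] * 3)
    with pytest.raises(InputError):
        select_common_degs(res_a, res_b)


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------

def probe_dataset():
    expr = pd.DataFrame(
        {
            "s1": [3.0, 5.0, 2.0, 7.0, 1.0],
            "s2": [3.2, 5.0, 2.0, 7.0, 1.0],
        },
        index=["p1", "p2", "p3", "p4", "p5"],
    )
    cond = pd.Series(["REF", "TEST1"], index=["s1", "s2"])
    return ExpressionDataset(expr, cond)


def test_maxmean_rule_picks_highest_mean_probe():
    data = probe_dataset()
    pm = pd.DataFrame(
        {"probe_id": ["p1", "p2", "p3", "p4"],
         "gene_symbol": ["G1", "G1", "G2", "G2"]}
    )
    out = collapse_probes(data, pm)
    assert list(out.genes) == ["G1", "G2"]
    assert np.allclose(out.expr.loc["G1"], data.expr.loc["p2"])  # mean 5 > 3.1
    assert np.allclose(out.expr.loc["G2"], data.expr.loc["p4"])


def test_multi_gene_probes_are_discarded():
    data = probe_dataset()
    pm = pd.DataFrame(
        {"probe_id": ["p1", "p1", "p3"], "gene_symbol": ["G1", "G2", "G3"]}
    )
    out = collapse_probes(data, pm)
    assert list(out.genes) == ["G3"]  # p1 ambiguous -> G1 and G2 gone


def test_one_to_one_map_is_a_relabelling():
    data = probe_dataset()
    pm = pd.DataFrame(
        {"probe_id": data.expr.index,
         "gene_symbol": [f"G_{p}" for p in data.expr.index]}
    )
    out = collapse_probes(data, pm)
    assert out.expr.shape == data.expr.shape
    assert np.allclose(
        out.expr.loc[sorted(out.genes)].values,
        data.expr.loc[[g[2:] for g in sorted(out.genes)]].values,
    )


def test_empty_map_is_an_error():
    with pytest.raises(InputError):
        collapse_probes(probe_dataset(), pd.DataFrame())


# ---------------------------------------------------------------------------
# outlier samples
# ---------------------------------------------------------------------------

def test_inflated_sample_is_flagged_exactly():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((500, 30))
        X[:, 7] *= 5.0
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(500)],
                            columns=[f"s{j}" for j in range(30)])
        cond = pd.Series(["REF"] * 30, index=expr.columns)
        out = detect_outlier_samples(ExpressionDataset(expr, cond), z_cut=-2.5)
        hits += out == ["s7"]
    assert hits == 20


def test_homogeneous_data_rarely_flags():
    counts = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        expr = pd.DataFrame(rng.standard_normal((200, 30)),
                            columns=[f"s{j}" for j in range(30)])
        cond = pd.Series(["REF"] * 30, index=expr.columns)
        counts.append(len(detect_outlier_samples(ExpressionDataset(expr, cond))))
    assert np.mean(counts) < 1.0


# ---------------------------------------------------------------------------
# good samples / genes
# ---------------------------------------------------------------------------

def test_complete_matrix_unchanged(rng):
    data = two_group_dataset(rng, n_genes=30)
    out = filter_good_samples_genes(data)
    assert out.expr.equals(data.expr)


def test_missingness_and_zero_variance_rules(rng):
    data = two_group_dataset(rng, n_genes=20, n_a=5, n_b=5)
    expr = data.expr.copy()
    expr.iloc[0, :6] = np.nan  # 60% missing -> removed
    expr.loc["g1", :] = 2.0  # constant -> removed
    out = filter_good_samples_genes(ExpressionDataset(expr, data.conditions), 0.5)
    assert "g0" not in out.genes and "g1" not in out.genes
    assert out.expr.shape[0] == 18
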