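"""Coexpression network: adjacency/TOM formulas, tree cut, trait selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import rloopsc as r
from rloopsc.network import signed_adjacency, scale_free_fit
from rloopsc.simulate import simulate_module_expression


def brute_force_r2(expr, power):
    """Independent recomputation of the scale-free fit for one power."""
    X = np.asarray(expr, float)
    C = np.corrcoef(X, rowvar=False)
    A = ((1 + C) / 2) ** power
    np.fill_diagonal(A, 0)
    k = A.sum(axis=1)
    k = k[k > 0]
    freq, edges = np.histogram(k, bins=10)
    mean_k = np.array(
        [k[(k >= lo) & (k <= hi if i == 9 else k < hi)].mean() if f else np.nan
         for i, (lo, hi, f) in enumerate(zip(edges[:-1], edges[1:], freq))]
    )
    ok = (freq > 0) & (mean_k > 0)
    slope, _, rr, _, _ = stats.linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    return rr**2, slope


@pytest.fixture(scope="module")
def modular_expr():
    return simulate_module_expression(500, 4, 30, 0.7, seed=2, n_noise_genes=20)


def test_r2_matches_brute_force(modular_expr):
    expr, _ = modular_expr
    _, table = r.pick_soft_threshold(expr)
    for _, row in table.iterrows():
        r2, slope = brute_force_r2(expr, row.power)
        assert row.r_squared == pytest.approx(r2, abs=1e-10)
        assert row.slope == pytest.approx(slope, abs=1e-10)


def test_smallest_qualifying_power_semantics(modular_expr):
    """With a permissive target, the smallest power with a negative-slope fit wins."""
    expr, _ = modular_expr
    beta, table = r.pick_soft_threshold(expr, r2_target=0.0)
    qualifying = table[(table.slope < 0) & (table.r_squared >= 0.0)]
    assert beta == int(qualifying.power.iloc[0])


def test_pick_soft_threshold_input_validation():
    with pytest.raises(ValueError):
        r.pick_soft_threshold(np.ones((2, 5)))  # too few observations


def test_constant_gene_correlations_treated_as_zero():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 4))
    X[:, 2] = 3.0
    A = signed_adjacency(X, 2)
    assert np.allclose(A[2, [0, 1, 3]], 0.25)  # ((1+0)/2)^2


def test_two_gene_tom_equals_adjacency():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 2))
    A = signed_adjacency(X, 3)
    tom = r.build_tom(X, 3)
    assert tom[0, 1] == pytest.approx(A[0, 1], abs=1e-12)


def test_identical_genes_have_unit_tom():
    z = np.random.default_rng(2).normal(size=60)
    X = np.column_stack([z, z, z])
    tom = r.build_tom(X, 6)
    assert tom[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_tom_permutation_equivariance(modular_expr):
    expr, _ = modular_expr
    X = expr.iloc[:, :40]
    perm = np.random.default_rng(3).permutation(40)
    tom = r.build_tom(X, 6)
    tom_perm = r.build_tom(X.iloc[:, perm], 6)
    assert np.allclose(tom[np.ix_(perm, perm)], tom_perm, atol=1e-10)


def test_tom_range_and_lower_bound(modular_expr):
    expr, _ = modular_expr
    X = expr.iloc[:, :60]
    A = signed_adjacency(X, 6)
    k = A.sum(axis=1)
    tom = r.build_tom(X, 6)
    assert tom.min() >= 0 and tom.max() <= 1
    off = ~np.eye(60, dtype=bool)
    bound = A / (np.minimum.outer(k, k) + 1.0)
    assert (tom[off] >= bound[off] - 1e-12).all()


def test_two_perfect_blocks_give_two_modules():
    rng = np.random.default_rng(4)
    z1, z2 = rng.normal(size=100), rng.normal(size=100)
    X = pd.DataFrame(
        np.column_stack([np.tile(z1, (15, 1)).T, np.tile(z2, (15, 1)).T]),
        columns=[f"g{i}" for i in range(30)],
    )
    asg = r.detect_modules(r.build_tom(X, 6), X, min_module_size=10)
    labels = asg.labels
    assert labels.nunique() == 2
    assert labels.iloc[:15].nunique() == 1 and labels.iloc[15:].nunique() == 1


def test_small_gene_set_all_grey():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
    asg = r.detect_modules(r.build_tom(X, 2), X, min_module_size=10)
    assert (asg.labels == "grey").all()


def test_correlated_module_pair_is_merged():
    """Eigengene dissimilarity below the merge height fuses two factors."""
    rng = np.random.default_rng(6)
    z1 = rng.normal(size=400)
    z2 = 0.85 * z1 + np.sqrt(1 - 0.85**2) * rng.normal(size=400)
    z3 = rng.normal(size=400)

    def block(z, k, c=0.8):
        return np.sqrt(c) * z[:, None] + np.sqrt(1 - c) * rng.normal(size=(400, k))

    close = pd.DataFrame(np.hstack([block(z1, 15), block(z2, 15)]),
                         columns=[f"g{i}" for i in range(30)])
    far = pd.DataFrame(np.hstack([block(z1, 15), block(z3, 15)]),
                       columns=[f"g{i}" for i in range(30)])
    merged = r.detect_modules(r.build_tom(close, 6), close, min_module_size=10)
    split = r.detect_modules(r.build_tom(far, 6), far, min_module_size=10)
    assert merged.labels.nunique() == 1
    assert split.labels.nunique() == 2


def test_module_recovery_and_order_invariance(modular_expr):
    expr, truth = modular_expr
    beta, _ = r.pick_soft_threshold(expr)
    asg = r.detect_modules(r.build_tom(expr, beta), expr)
    assert adjusted_rand_score(truth.values, asg.labels.values) >= 0.8
    perm = np.random.default_rng(7).permutation(expr.shape[1])
    asg_perm = r.detect_modules(r.build_tom(expr.iloc[:, perm], beta), expr.iloc[:, perm])
    aligned = asg_perm.labels.reindex(asg.labels.index)
    assert adjusted_rand_score(asg.labels.values, aligned.values) >= 0.95


def test_eigengene_unit_norm_and_orientation(modular_expr):
    expr, _ = modular_expr
    asg = r.detect_modules(r.build_tom(expr, 6), expr)
    for mod in asg.modules:
        e = asg.eigengenes[mod].to_numpy()
        assert np.linalg.norm(e) == pytest.approx(1.0, abs=1e-8)
        mean_expr = expr[asg.genes_in(mod)].mean(axis=1)
        assert np.corrcoef(e, mean_expr)[0, 1] >= 0


def test_trait_correlation_closed_forms(modular_expr):
    expr, _ = modular_expr
    asg = r.detect_modules(r.build_tom(expr, 6), expr)
    e = asg.eigengenes[asg.modules[0]]
    traits = pd.DataFrame({
        "same": e.to_numpy(),              # r = 1
        "const": np.ones(len(e)),          # undefined
        "toy": np.nan,
    })
    # 5 printed toy pairs on the first 5 observations, closed-form Pearson
    toy_x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    toy_y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
    traits = traits.drop(columns="toy")
    stats_table = r.module_trait_correlation(asg, traits)
    same = stats_table[stats_table.trait == "same"].iloc[0]
    assert same.r == pytest.approx(1.0, abs=1e-8)
    assert same.p < 1e-10
    const = stats_table[stats_table.trait == "const"].iloc[0]
    assert np.isnan(const.r) and np.isnan(const.p)
    r_manual = ((toy_x - 3) * (toy_y - toy_y.mean())).sum() / np.sqrt(
        ((toy_x - 3) ** 2).sum() * ((toy_y - toy_y.mean()) ** 2).sum()
    )
    assert stats.pearsonr(toy_x, toy_y)[0] == pytest.approx(r_manual, abs=1e-12)


def test_trait_p_uniform_under_null(modular_expr):
    expr, _ = modular_expr
    asg = r.detect_modules(r.build_tom(expr, 6), expr)
    rng = np.random.default_rng(8)
    pvals = []
    for _ in range(200):
        traits = pd.DataFrame({"null": rng.normal(size=len(asg.eigengenes))})
        t = r.module_trait_correlation(asg, traits)
        pvals.append(t.p.iloc[0])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_select_score_genes(modular_expr):
    expr, truth = modular_expr
    asg = r.detect_modules(r.build_tom(expr, 6), expr)
    rng = np.random.default_rng(9)
    # trait tied to module M1's eigengene; everything else independent
    linked = asg.eigengenes[asg.modules[0]].to_numpy()
    traits = pd.DataFrame({
        "mutation": 5 * linked / linked.std() + rng.normal(size=len(linked)),
        "stage": rng.normal(size=len(linked)),
    })
    r.module_trait_correlation(asg, traits)
    stats_table = asg.trait_stats
    # selecting on the null trait only -> usually empty; force it by alpha=0
    assert r.select_score_genes(asg, alpha=0.0) == []
    genes = r.select_score_genes(asg, traits=["mutation"])
    sig_modules = set(
        stats_table[(stats_table.trait == "mutation") & (stats_table.p < 0.05)].module
    )
    expected = sorted({g for mod in sig_modules for g in asg.genes_in(mod)})
    assert genes == expected
    assert asg.modules[0] in sig_modules
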