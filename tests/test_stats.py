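"""Group statistics: cluster permutation test, ANOVA/MANOVA oracles,
correlations, effect sizes, power approximations and p corrections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp

from mertopo import stats
from mertopo.exceptions import InsufficientDataError


GRID = np.arange(10.0, -5.0 - 1e-9, -0.5)


# --- cluster permutation test ------------------------------------------------

def test_cluster_identical_groups_no_clusters(rng):
    A = rng.normal(0, 1, (10, GRID.size))
    res = stats.cluster_permutation_test(A, A.copy(), GRID, n_perm=200, seed=0)
    assert res.significant() == []


def test_cluster_recovers_injected_interval(rng):
    """An offset injected on depths [3.6, 1.2] is recovered as one
    significant cluster covering >= 80% of the injected interval."""
    inj = (GRID <= 3.6) & (GRID >= 1.2)
    A = rng.normal(0, 0.3, (30, GRID.size))
    B = rng.normal(0, 0.3, (30, GRID.size))
    B[:, inj] += 2.0
    res = stats.cluster_permutation_test(A, B, GRID, n_perm=1000, seed=4)
    sig = res.significant()
    assert len(sig) >= 1
    covered = np.zeros(GRID.size, bool)
    for c in sig:
        covered |= (GRID <= c.depth_start) & (GRID >= c.depth_end)
    assert (covered & inj).sum() / inj.sum() >= 0.8


def test_cluster_handles_missing_cells(rng):
    A = rng.normal(0, 1, (8, GRID.size))
    B = rng.normal(0, 1, (8, GRID.size))
    A[:, 5] = np.nan  # a depth with no group-A data never joins a cluster
    A[0, ::3] = np.nan
    res = stats.cluster_permutation_test(A, B, GRID, n_perm=200, seed=1)
    for c in res.clusters:
        assert not (c.depth_start >= GRID[5] >= c.depth_end)


def test_cluster_paired_mode(rng):
    A = rng.normal(0, 0.5, (20, GRID.size))
    B = A + 1.5 + rng.normal(0, 0.2, A.shape)  # near-constant paired offset
    res = stats.cluster_permutation_test(A, B, GRID, n_perm=500, seed=2, paired=True)
    assert len(res.significant()) >= 1


def test_cluster_degenerate_inputs(rng):
    with pytest.raises(ValueError):
        stats.cluster_permutation_test(
            rng.normal(size=(1, GRID.size)), rng.normal(size=(5, GRID.size)), GRID
        )


# --- ANOVA -------------------------------------------------------------------

def test_anova_oneway_brute_force_oracle(rng):
    """F from explicit sums of squares matches to 1e-8."""
    a = rng.normal(0, 1, 23)
    b = rng.normal(0.6, 1.3, 31)
    grand = np.mean(np.concatenate([a, b]))
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    f_oracle = (ss_between / 1) / (ss_within / (a.size + b.size - 2))
    res = stats.anova_oneway(a, b)
    assert res.statistic == pytest.approx(f_oracle, rel=1e-8)
    assert res.df == (1, a.size + b.size - 2)


def test_anova_oneway_equal_groups(rng):
    a = rng.normal(5, 1, 40)
    res = stats.anova_oneway(a, a + rng.normal(0, 1e-2, 40) * 0)
    assert res.p > 0.9  # identical distributions relabelled
    with pytest.raises(ValueError):
        stats.anova_oneway(np.ones(10), np.ones(12))


def test_anova_twoway_type2_and_null_interaction(rng):
    """A pure factor-B main effect rarely produces an interaction."""
    false_pos = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        n = 40
        fa = np.repeat(["s1", "s2"], 2 * n)
        fb = np.tile(np.repeat(["c1", "c2"], n), 2)
        y = r.normal(0, 1, 4 * n) + (fb == "c2") * 1.0
        res = stats.anova_twoway(y, fa, fb)
        if res["interaction"].p < 0.05:
            false_pos += 1
        assert res["anesthesia"].statistic_name == "F"
    assert false_pos <= 2  # interaction significant in <= 10% of runs


def test_anova_twoway_empty_cell():
    with pytest.raises(InsufficientDataError):
        stats.anova_twoway([1.0, 2.0, 3.0], ["a", "a", "b"], ["x", "x", "x"])


# --- MANOVA ------------------------------------------------------------------

def test_manova_eigenvalue_oracle(rng):
    """Wilks Lambda equals prod 1/(1+eig(W^-1 B)) to 1e-8."""
    groups = [rng.normal(m, 1, (25, 3)) for m in (0.0, 0.5, 1.0)]
    res = stats.manova(groups)
    allx = np.vstack(groups)
    grand = allx.mean(axis=0)
    W = sum((g - g.mean(0)).T @ (g - g.mean(0)) for g in groups)
    B = sum(len(g) * np.outer(g.mean(0) - grand, g.mean(0) - grand) for g in groups)
    eig = np.linalg.eigvals(np.linalg.solve(W, B)).real
    lam_oracle = np.prod(1.0 / (1.0 + eig))
    assert res.statistic == pytest.approx(lam_oracle, rel=1e-8)


def test_manova_against_statsmodels(rng):
    from statsmodels.multivariate.manova import MANOVA

    groups = [rng.normal(m, 1, (20, 3)) for m in (0.0, 0.8)]
    res = stats.manova(groups)
    y = np.vstack(groups)
    g = np.repeat(["a", "b"], 20)
    sm_res = MANOVA(y, np.column_stack([np.ones(40), g == "b"]).astype(float))
    tab = sm_res.mv_test().results["x1"]["stat"]
    assert res.statistic == pytest.approx(tab.loc["Wilks' lambda", "Value"], rel=1e-6)


def test_manova_relabelled_identical_groups(rng):
    x = rng.normal(0, 1, (40, 3))
    res = stats.manova([x[::2], x[1::2]])
    assert res.statistic > 0.8  # Lambda near 1


def test_manova_separated_on_z_only(rng):
    base = rng.normal(0, 0.2, (3, 20, 3))
    for i, dz in enumerate((0.0, 3.0, 6.0)):
        base[i, :, 2] += dz
    res = stats.manova(list(base))
    assert res.statistic < 0.05 and res.p < 1e-6


# --- Spearman ----------------------------------------------------------------

def test_spearman_monotone():
    x = np.arange(10.0)
    assert stats.spearman(x, x**3).statistic == pytest.approx(1.0)
    assert stats.spearman(x, -x).statistic == pytest.approx(-1.0)


def test_spearman_tied_rank_oracle():
    """Average-rank Pearson on a small tied dataset, computed by hand."""
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0])
    y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 6.0, 8.0])
    rx = sp.rankdata(x)
    ry = sp.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert stats.spearman(x, y).statistic == pytest.approx(oracle, abs=1e-12)


def test_spearman_bonferroni_and_errors():
    x = np.arange(20.0)
    y = x + np.sin(x)
    res = stats.spearman(x, y, n_comparisons=4)
    assert res.p == pytest.approx(min(1.0, res.extra["p_uncorrected"] * 4))
    with pytest.raises(ValueError):
        stats.spearman(np.ones(10), np.arange(10.0))


# --- effect sizes and power --------------------------------------------------

def test_cohen_d_large_sample(rng):
    a = rng.normal(0, 1, 100_000)
    b = rng.normal(1, 1, 100_000)
    assert stats.cohen_d_two_sample(a, b) == pytest.approx(1.0, abs=0.02)
    assert stats.cohen_d_two_sample([1.0, 2.0], [1.0, 2.0]) == 0.0
    with pytest.raises(ValueError):
        stats.cohen_d_two_sample([0.0, 0.0], [1.0, 1.0])


def test_d_from_r_values():
    assert stats.d_from_r(0.0) == 0.0
    assert round(stats.d_from_r(0.278), 2) == 0.58
    with pytest.raises(ValueError):
        stats.d_from_r(1.0)


def test_power_correlation_limits():
    assert stats.power_correlation(0.0, 100) == pytest.approx(0.05, abs=1e-9)
    assert stats.power_correlation(0.9, 100) == pytest.approx(1.0, abs=1e-6)


def test_power_two_sample_null_and_monotone():
    assert stats.power_two_sample(0.0, 50, 50) == pytest.approx(0.05, abs=1e-9)
    p = [stats.power_two_sample(d, 40, 40) for d in (0.1, 0.3, 0.5, 0.8)]
    assert np.all(np.diff(p) > 0)
    p_n = [stats.power_two_sample(0.4, n, n) for n in (10, 40, 160)]
    assert np.all(np.diff(p_n) > 0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    p1=st.floats(0.0, 1.0), p2=st.floats(0.0, 1.0), m=st.integers(1, 10)
)
def test_corrections_monotone(p1, p2, m):
    """Larger raw p never yields smaller corrected p."""
    lo, hi = sorted([p1, p2])
    b = stats.bonferroni([lo, hi], m)
    assert b[0] <= b[1]
    f = stats.bh_fdr([lo, hi])
    assert f[0] <= f[1] + 1e-12


def test_bonferroni_values():
    np.testing.assert_allclose(stats.bonferroni([0.01, 0.04], 4), [0.04, 0.16])


def test_bh_fdr_step_up_by_hand():
    # by hand: p_(i) * m / i = .04, .04, .04, .04 -> all 0.04
    np.testing.assert_allclose(stats.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(stats.bh_fdr([0.2]), [0.2])
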