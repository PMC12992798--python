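"""Group-level statistics for depth-resolved MER analyses.

Covers the statistical layer of the analysis: a cluster-based permutation
test for depth profiles (controls the family-wise error across recording
depths), one- and two-way ANOVA and MANOVA with Cohen-style effect sizes
and post hoc power, Spearman correlations with Bonferroni control,
Benjamini–Hochberg FDR, and the effect-size/power conversions used when
reporting (d = 2r/sqrt(1-r^2); Fisher-z and noncentral-F power).

Results are returned as small Results-style objects (:class:`TestSummary`,
:class:`ClusterResult`) with ``summary()`` methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError

__all__ = [
    "TestSummary",
    "Cluster",
    "ClusterResult",
    "cluster_permutation_test",
    "anova_oneway",
    "anova_twoway",
    "manova",
    "spearman",
    "d_from_r",
    "power_correlation",
    "power_two_sample",
    "power_anova",
    "bonferroni",
    "bh_fdr",
    "cohen_d_two_sample",
]


@dataclass
class TestSummary:
    """One statistical test: statistic, df, p, effect size, power."""

    name: str
    statistic: float
    statistic_name: str  # "F" | "Lambda" | "t" | "rho"
    df: tuple
    p: float
    cohen_d: float | None = None
    posthoc_power: float | None = None
    correction: str = "none"
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        df_txt = ",".join(f"{d:g}" for d in self.df)
        parts = [
            f"{self.name}: {self.statistic_name}({df_txt}) = {self.statistic:.3f}",
            f"p = {self.p:.4g}",
        ]
        if self.cohen_d is not None:
            parts.append(f"d = {self.cohen_d:.2f}")
        if self.posthoc_power is not None:
            parts.append(f"power = {self.posthoc_power:.3f}")
        if self.correction != "none":
            parts.append(f"correction = {self.correction}")
        return ", ".join(parts)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "statistic_name": self.statistic_name,
            "df": list(self.df),
            "p": self.p,
            "cohen_d": self.cohen_d,
            "posthoc_power": self.posthoc_power,
            "correction": self.correction,
            **{k: v for k, v in self.extra.items()},
        }


@dataclass
class Cluster:
    depth_start: float  # dorsal bound (larger depth-to-target)
    depth_end: float  # ventral bound
    mass: float  # signed sum of the pointwise t statistics
    p: float  # permutation p, BH-corrected across clusters


@dataclass
class ClusterResult:
    """Clusters of contiguous depths with a significant group difference."""

    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    grid: np.ndarray
    t_values: np.ndarray

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p <= a]

    def summary(self) -> str:
        if not self.clusters:
            return f"no suprathreshold clusters ({self.n_permutations} permutations)"
        lines = [
            f"cluster {c.depth_start:+.1f} to {c.depth_end:+.1f} mm: "
            f"mass = {c.mass:.1f}, p = {c.p:.4f}"
            for c in self.clusters
        ]
        return "\n".join(lines)


def _nan_two_sample_t(
    X0: np.ndarray, M: np.ndarray, G: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per column for many group assignments.

    ``X0`` is the data with NaN replaced by 0, ``M`` the finite mask,
    ``G`` a (n_perm, n_rows) 0/1 matrix selecting group A.  Returns
    (t, n1, n2), each (n_perm, n_cols).
    """
    Gc = 1.0 - G
    n1 = G @ M
    n2 = Gc @ M
    s1 = G @ X0
    s2 = Gc @ X0
    ss1 = G @ (X0 * X0 * M)
    ss2 = Gc @ (X0 * X0 * M)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m2 = s2 / n2
        v1 = (ss1 - n1 * m1**2) / np.maximum(n1 - 1, 1)
        v2 = (ss2 - n2 * m2**2) / np.maximum(n2 - 1, 1)
        sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(n1 + n2 - 2, 1)
        t = (m1 - m2) / np.sqrt(sp * (1.0 / n1 + 1.0 / n2))
    t[~np.isfinite(t)] = 0.0
    return t, n1, n2


def _max_cluster_mass(t: np.ndarray, supra: np.ndarray) -> np.ndarray:
    """Maximum |cluster mass| per row; clusters are sign-consistent runs.

    Vectorised over rows with a single sweep over columns."""
    n_perm = t.shape[0]
    cur_pos = np.zeros(n_perm)
    cur_neg = np.zeros(n_perm)
    best = np.zeros(n_perm)
    for j in range(t.shape[1]):
        tj = t[:, j]
        sj = supra[:, j]
        pos = sj & (tj > 0)
        neg = sj & (tj < 0)
        cur_pos = np.where(pos, cur_pos + tj, 0.0)
        cur_neg = np.where(neg, cur_neg - tj, 0.0)
        best = np.maximum(best, np.maximum(cur_pos, cur_neg))
    return best


def cluster_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    grid: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    paired: bool = False,
) -> ClusterResult:
    """Cluster-based permutation test between two sets of depth profiles.

    ``group_a``/``group_b`` are (n_profiles, n_depths) arrays on a common
    depth ``grid`` (NaN = missing).  A pooled two-sample t is computed at
    each depth; depths with pointwise p below ``cluster_alpha`` form
    sign-consistent contiguous clusters whose mass is the sum of their t
    values.  Significance comes from the permutation null of the maximum
    absolute cluster mass under ``n_perm`` random relabellings of the
    profiles (sign flips of the paired differences when ``paired``);
    cluster p-values are Benjamini–Hochberg corrected across clusters.

    Depths where either group has fewer than two finite values never join
    a cluster.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if A.shape[1] != grid.size or B.shape[1] != grid.size:
        raise ValueError("profiles and grid have mismatched lengths")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 profiles per group")
    rng = np.random.default_rng(seed)

    if paired:
        if A.shape[0] != B.shape[0]:
            raise ValueError("paired test needs equal group sizes")
        D = A - B
        M = np.isfinite(D).astype(float)
        X0 = np.where(np.isfinite(D), D, 0.0)
        n = M.sum(axis=0)
        valid = n >= 2

        def one_sample_t(signs):
            s = signs @ X0
            ns = np.abs(signs) @ M  # = n, constant
            mean = s / np.maximum(ns, 1)
            ss = np.ones(signs.shape[0])[:, None] * (X0 * X0 * M).sum(axis=0)
            var = (ss - ns * mean**2) / np.maximum(ns - 1, 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = mean / np.sqrt(var / np.maximum(ns, 1))
            t[~np.isfinite(t)] = 0.0
            return t

        t_obs = one_sample_t(np.ones((1, D.shape[0])))[0]
        df = np.maximum(n - 1, 1)
        t_crit = sp_stats.t.ppf(1 - cluster_alpha / 2, df)
        supra_obs = valid & (np.abs(t_obs) > t_crit)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, D.shape[0]))
        t_null = one_sample_t(signs)
        supra_null = valid[None, :] & (np.abs(t_null) > t_crit[None, :])
        null_max = _max_cluster_mass(t_null, supra_null)
    else:
        X = np.vstack([A, B])
        M = np.isfinite(X).astype(float)
        X0 = np.where(np.isfinite(X), X, 0.0)
        nA = A.shape[0]
        n = X.shape[0]
        g_obs = np.zeros((1, n))
        g_obs[0, :nA] = 1.0
        t_obs_arr, n1, n2 = _nan_two_sample_t(X0, M, g_obs)
        t_obs = t_obs_arr[0]
        valid = (n1[0] >= 2) & (n2[0] >= 2)
        df = np.maximum(n1[0] + n2[0] - 2, 1)
        t_crit = sp_stats.t.ppf(1 - cluster_alpha / 2, df)
        supra_obs = valid & (np.abs(t_obs) > t_crit)
        # label permutations with fixed group sizes
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        G = np.zeros((n_perm, n))
        np.put_along_axis(G, order[:, :nA], 1.0, axis=1)
        t_null, pn1, pn2 = _nan_two_sample_t(X0, M, G)
        supra_null = (
            valid[None, :]
            & (np.abs(t_null) > t_crit[None, :])
            & (pn1 >= 2)
            & (pn2 >= 2)
        )
        null_max = _max_cluster_mass(t_null, supra_null)

    # observed clusters: contiguous sign-consistent suprathreshold runs
    clusters: list[Cluster] = []
    j = 0
    k = grid.size
    while j < k:
        if supra_obs[j]:
            sign = np.sign(t_obs[j])
            start = j
            while j < k and supra_obs[j] and np.sign(t_obs[j]) == sign:
                j += 1
            mass = float(t_obs[start:j].sum())
            p = float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm))
            clusters.append(
                Cluster(
                    depth_start=float(grid[start]),
                    depth_end=float(grid[j - 1]),
                    mass=mass,
                    p=p,
                )
            )
        else:
            j += 1
    if clusters:
        corrected = bh_fdr([c.p for c in clusters])
        for c, pc in zip(clusters, corrected):
            c.p = float(pc)
    return ClusterResult(
        clusters=clusters,
        n_permutations=n_perm,
        alpha=alpha,
        grid=grid,
        t_values=t_obs,
    )


# --- effect sizes and power --------------------------------------------------

def cohen_d_two_sample(a: Sequence[float], b: Sequence[float]) -> float:
    """|mean difference| over the pooled (n-1 weighted) SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if pooled <= 0:
        raise ValueError("zero pooled variance")
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled))


def d_from_r(rho: float) -> float:
    """Cohen's d equivalent of a correlation: 2|r| / sqrt(1 - r^2)."""
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    return float(2 * abs(rho) / np.sqrt(1 - rho**2))


def _f_to_d(f_stat: float, df1: float, df2: float) -> float:
    """Cohen's d equivalent of an F effect: d = 2 f, f^2 = df1 F / df2."""
    return float(2 * np.sqrt(max(df1 * f_stat, 0.0) / df2))


def power_correlation(rho: float, n: int, alpha: float = 0.05) -> float:
    """Post hoc power of a two-sided correlation test (Fisher z).

    power = Phi(z sqrt(n-3) - z_crit) + Phi(-z sqrt(n-3) - z_crit) with
    z = atanh(|rho|).
    """
    if n <= 3:
        raise ValueError("need n > 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = np.arctanh(abs(rho))
    zc = sp_stats.norm.ppf(1 - alpha / 2)
    lam = z * np.sqrt(n - 3)
    return float(sp_stats.norm.cdf(lam - zc) + sp_stats.norm.cdf(-lam - zc))


def power_two_sample(
    d: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    allocation: str = "unequal",
) -> float:
    """Post hoc power of a two-sided two-sample test (normal approximation).

    ``allocation="unequal"`` (default) uses ncp = d sqrt(n1 n2/(n1+n2));
    ``"equal"`` splits the total sample evenly, ncp = d sqrt((n1+n2)/4).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if allocation == "unequal":
        ncp = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    elif allocation == "equal":
        ncp = abs(d) * np.sqrt((n1 + n2) / 4.0)
    else:
        raise ValueError("allocation must be 'unequal' or 'equal'")
    zc = sp_stats.norm.ppf(1 - alpha / 2)
    return float(sp_stats.norm.cdf(ncp - zc) + sp_stats.norm.cdf(-ncp - zc))


def power_anova(
    f_stat: float, df1: float, df2: float, n_total: int, alpha: float = 0.05
) -> float:
    """Post hoc power of an F test via the noncentral F distribution.

    The noncentrality is lambda = f^2 N with f^2 = df1 F / df2 (the
    observed Cohen's f-squared).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lam = max(df1 * f_stat, 0.0) / df2 * n_total
    f_crit = sp_stats.f.ppf(1 - alpha, df1, df2)
    if lam <= 0:  # central case: power equals the test size
        return alpha
    return float(sp_stats.ncf.sf(f_crit, df1, df2, lam))


# --- multiple comparisons ----------------------------------------------------

def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, m p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR correction."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# --- ANOVA / MANOVA / correlation -------------------------------------------

def anova_oneway(
    *groups: Sequence[float], name: str = "oneway", alpha: float = 0.05
) -> TestSummary:
    """One-way ANOVA with Cohen's-f-based effect size and noncentral-F power."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise InsufficientDataError("need at least 2 observations per group")
    allv = np.concatenate(gs)
    if np.allclose(allv, allv[0]):
        raise ValueError("all observations identical; F undefined")
    f_stat, p = sp_stats.f_oneway(*gs)
    f_stat = float(max(f_stat, 0.0))  # guard tiny negative round-off
    k = len(gs)
    n = allv.size
    df1, df2 = k - 1, n - k
    if not np.isfinite(p):
        p = float(sp_stats.f.sf(f_stat, df1, df2))
    d = _f_to_d(f_stat, df1, df2)
    return TestSummary(
        name=name,
        statistic=float(f_stat),
        statistic_name="F",
        df=(df1, df2),
        p=float(p),
        cohen_d=d,
        posthoc_power=power_anova(f_stat, df1, df2, n, alpha),
        extra={"group_sizes": [int(g.size) for g in gs]},
    )


def anova_twoway(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    names: tuple[str, str] = ("structure", "anesthesia"),
    alpha: float = 0.05,
) -> dict[str, TestSummary]:
    """Two-way ANOVA with Type-II sums of squares (unbalanced design).

    Returns TestSummary objects keyed by the two factor names plus
    ``"interaction"``.  Effect sizes and power follow the same
    f-squared conventions as :func:`anova_oneway`.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float), "fa": factor_a, "fb": factor_b}
    )
    cells = df.groupby(["fa", "fb"]).size()
    if (cells < 2).any():
        raise InsufficientDataError("every factor cell needs >= 2 observations")
    model = smf.ols("value ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(table.loc["Residual", "df"])
    n = len(df)
    out: dict[str, TestSummary] = {}
    for row, key in (
        ("C(fa)", names[0]),
        ("C(fb)", names[1]),
        ("C(fa):C(fb)", "interaction"),
    ):
        f_stat = float(table.loc[row, "F"])
        df1 = float(table.loc[row, "df"])
        p = float(table.loc[row, "PR(>F)"])
        out[key] = TestSummary(
            name=key,
            statistic=f_stat,
            statistic_name="F",
            df=(df1, df_resid),
            p=p,
            cohen_d=_f_to_d(f_stat, df1, df_resid),
            posthoc_power=power_anova(f_stat, df1, df_resid, n, alpha),
        )
    return out


def manova(
    groups: Sequence[np.ndarray], name: str = "manova", alpha: float = 0.05
) -> TestSummary:
    """One-way MANOVA via Wilks' Lambda with Rao's F approximation.

    ``groups`` is a sequence of (n_i, p) observation matrices.  Lambda =
    det(W) / det(W + B) with W and B the within- and between-group scatter
    matrices.
    """
    gs = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    p = gs[0].shape[1]
    if any(g.shape[1] != p for g in gs):
        raise ValueError("all groups must share the same dimensionality")
    if any(g.shape[0] < p + 1 for g in gs):
        raise InsufficientDataError(f"need at least {p + 1} observations per group")
    k = len(gs)
    allx = np.vstack(gs)
    n = allx.shape[0]
    grand = allx.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in gs:
        mu = g.mean(axis=0)
        cen = g - mu
        W += cen.T @ cen
        diff = (mu - grand)[:, None]
        B += g.shape[0] * (diff @ diff.T)
    T = W + B
    det_T = np.linalg.det(T)
    if det_T <= 0 or np.linalg.det(W) <= 0:
        raise ValueError("singular scatter matrix")
    lam = float(np.linalg.det(W) / det_T)

    # Rao's F approximation
    a = n - 1 - (p + k) / 2.0
    num = p**2 * (k - 1) ** 2 - 4
    den = p**2 + (k - 1) ** 2 - 5
    s = np.sqrt(num / den) if den > 0 else 1.0
    df1 = p * (k - 1)
    df2 = a * s - (p * (k - 1) - 2) / 2.0
    lam_s = lam ** (1.0 / s)
    f_stat = (1 - lam_s) / lam_s * df2 / df1
    p_val = float(sp_stats.f.sf(f_stat, df1, df2))
    return TestSummary(
        name=name,
        statistic=lam,
        statistic_name="Lambda",
        df=(df1, df2),
        p=p_val,
        cohen_d=_f_to_d(f_stat, df1, df2),
        posthoc_power=power_anova(f_stat, df1, df2, n, alpha),
        extra={"F": float(f_stat)},
    )


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    n_comparisons: int = 1,
    name: str = "spearman",
    alpha: float = 0.05,
) -> TestSummary:
    """Spearman rank correlation with Bonferroni-multiplied p.

    Ties receive average ranks.  The effect size is the d-equivalent of
    rho, and post hoc power uses the Fisher-z approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input; rho undefined")
    rho, p = sp_stats.spearmanr(x, y)
    rho = float(rho)
    p_corr = min(1.0, float(p) * n_comparisons)
    perfect = abs(rho) >= 1.0
    return TestSummary(
        name=name,
        statistic=rho,
        statistic_name="rho",
        df=(x.size - 2,),
        p=p_corr,
        cohen_d=None if perfect else d_from_r(rho),
        posthoc_power=1.0 if perfect else power_correlation(rho, x.size, alpha),
        correction="bonferroni" if n_comparisons > 1 else "none",
        extra={"n": int(x.size), "p_uncorrected": float(p)},
    )
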