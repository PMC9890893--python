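"""Group-comparison statistics and the study's test-selection rule.

The analyses in this package never pick a hypothesis test ad hoc: a single
decision rule maps the design (group sizes, pairing, number of groups, an
F-test of variances) onto one of five tests, so every comparison is
reproducible from the data alone.

Rule
----
* more than 7 per group  -> rank-based tests (Kruskal-Wallis with
  uncorrected Dunn pairwise comparisons for 3+ groups, Wilcoxon rank-sum
  for 2 groups), robust to non-normality and unequal variances;
* 7 or fewer per group   -> unpaired t test when a two-sided F-test finds
  the variances similar (nonparametric tests have very low power at such
  sizes), Welch's t test when it does not;
* paired designs         -> Wilcoxon matched-pairs signed-rank test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TestPlan",
    "TestResult",
    "choose_test",
    "kruskal_dunn",
    "ranksum",
    "signed_rank",
    "t_test",
    "f_test_var",
    "ancova_slopes",
    "run_comparison",
]

VALID_TESTS = ("kruskal_dunn", "ranksum", "signed_rank", "t_unpaired", "t_welch")


@dataclass(frozen=True)
class TestPlan:
    """Outcome of the test-selection rule.

    Attributes
    ----------
    test : str
        One of ``kruskal_dunn``, ``ranksum``, ``signed_rank``,
        ``t_unpaired``, ``t_welch``.
    rationale : str
        Human-readable trace of the decision (sample sizes, F-test p).
    """

    test: str
    rationale: str

    def __post_init__(self) -> None:
        if self.test not in VALID_TESTS:
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    pairwise: dict = field(default_factory=dict)  # (i, j) -> p, for Dunn


def choose_test(
    group_sizes,
    *,
    paired: bool = False,
    n_groups: int | None = None,
    variance_f_test_p: float | None = None,
    alpha_var: float = 0.05,
) -> TestPlan:
    """Select the hypothesis test for a comparison.

    Parameters
    ----------
    group_sizes : sequence of int
        Number of observations per group.
    paired : bool
        Matched-pairs design; dispatches straight to the signed-rank test.
    n_groups : int, optional
        Defaults to ``len(group_sizes)``.
    variance_f_test_p : float, optional
        p-value of an F-test of equal variances; required only when the
        small-sample branch is reached with two groups.
    alpha_var : float
        Significance level for "similar variances" (default 0.05).
    """
    sizes = [int(s) for s in group_sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("every group must contain at least one observation")
    if n_groups is None:
        n_groups = len(sizes)
    if paired:
        return TestPlan("signed_rank", f"paired design, n={sizes[0]} pairs")
    if max(sizes) > 7:
        if n_groups >= 3:
            return TestPlan(
                "kruskal_dunn",
                f"sizes {sizes} > 7, {n_groups} groups -> Kruskal-Wallis "
                "with uncorrected Dunn pairwise comparisons",
            )
        return TestPlan("ranksum", f"sizes {sizes} > 7, 2 groups -> Wilcoxon rank-sum")
    if variance_f_test_p is None:
        raise ValueError(
            "sample sizes <= 7: a variance F-test p-value is required to choose "
            "between the unpaired and Welch t tests"
        )
    if variance_f_test_p >= alpha_var:
        return TestPlan(
            "t_unpaired",
            f"sizes {sizes} <= 7, F-test p={variance_f_test_p:.3g} >= "
            f"{alpha_var} (similar variances) -> unpaired t test",
        )
    return TestPlan(
        "t_welch",
        f"sizes {sizes} <= 7, F-test p={variance_f_test_p:.3g} < {alpha_var} "
        "(different variances) -> Welch's t test",
    )


def f_test_var(a, b) -> TestResult:
    """Two-sided F-test of equal variances between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("F-test needs at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return TestResult("f_var", 1.0, 1.0)
    if va == 0.0 or vb == 0.0:
        return TestResult("f_var", float("inf"), 0.0)
    # convention: larger variance in the numerator, two-sided p
    if va >= vb:
        f, dfn, dfd = va / max(vb, np.finfo(float).tiny), a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / max(va, np.finfo(float).tiny), b.size - 1, a.size - 1
    p = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    return TestResult("f_var", float(f), float(p))


def t_test(a, b, *, welch: bool = False) -> TestResult:
    """Two-sided unpaired t test (pooled variance, or Welch if requested)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=not welch)
    return TestResult("t_welch" if welch else "t_unpaired", float(res.statistic), float(res.pvalue))


def ranksum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution for small tie-free samples, normal
    approximation with tie correction otherwise (scipy's ``auto`` policy).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("rank-sum needs at least 2 observations per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult("ranksum", float(res.statistic), float(res.pvalue))


def signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    ``x`` may be the paired differences directly, or the first member of
    each pair with ``y`` the second. All-zero differences return p = 1.
    """
    x = np.asarray(x, float)
    d = x if y is None else x - np.asarray(y, float)
    if d.size < 1:
        raise ValueError("signed-rank needs at least one pair")
    if np.all(d == 0):
        import warnings

        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult("signed_rank", 0.0, 1.0)
    res = stats.wilcoxon(d, alternative="two-sided", method="auto")
    return TestResult("signed_rank", float(res.statistic), float(res.pvalue))


def kruskal_dunn(groups) -> TestResult:
    """Kruskal-Wallis omnibus test plus uncorrected Dunn pairwise z-tests.

    Pairwise comparisons use Dunn's z statistic on the pooled ranks with
    the standard tie correction; the pairwise p-values are deliberately NOT
    adjusted for multiplicity.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_dunn needs at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_dunn", 0.0, 1.0,
                          {(i, j): 1.0 for i, j in itertools.combinations(range(len(groups)), 2)})
    h, p = stats.kruskal(*groups)

    ranks = stats.rankdata(pooled)
    n = pooled.size
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    pairwise: dict = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        pairwise[(i, j)] = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult("kruskal_dunn", float(h), float(p), pairwise)


def ancova_slopes(points_a, points_b) -> TestResult:
    """F-test of equal regression slopes between two (x, y) clouds.

    Fits the two-line model y = a_g + b_g x per group and tests the
    group-by-x interaction (equality of the two slopes) against the
    common-slope model.
    """
    xa, ya = _split_xy(points_a)
    xb, yb = _split_xy(points_b)
    for x, name in ((xa, "a"), (xb, "b")):
        if x.size < 3:
            raise ValueError(f"group {name} needs at least 3 points")
        if np.ptp(x) == 0:
            raise ValueError(f"x is constant in group {name}")
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
    # full model: intercept, group, x, group*x
    X_full = np.column_stack([np.ones_like(x), g, x, g * x])
    X_red = X_full[:, :3]
    rss_full = _rss(X_full, y)
    rss_red = _rss(X_red, y)
    df_resid = x.size - 4
    if df_resid < 1:
        raise ValueError("too few points for the interaction F-test")
    if rss_full <= 1e-12 * max(1.0, float(y @ y)):
        # both lines fit exactly; identical slopes give F = 0
        sa = np.polyfit(xa, ya, 1)[0]
        sb = np.polyfit(xb, yb, 1)[0]
        if math.isclose(sa, sb, rel_tol=1e-12, abs_tol=1e-12):
            return TestResult("ancova_slopes", 0.0, 1.0)
        return TestResult("ancova_slopes", float("inf"), 0.0)
    f = (rss_red - rss_full) / (rss_full / df_resid)
    p = float(stats.f.sf(f, 1, df_resid))
    return TestResult("ancova_slopes", float(f), p)


def run_comparison(groups, *, paired: bool = False, alpha_var: float = 0.05):
    """Apply the full decision rule to raw data: choose the test, run it.

    Returns ``(TestPlan, TestResult)``. For two unpaired small groups the
    variance F-test is computed here and folded into the plan rationale.
    """
    arrays = [np.asarray(g, float) for g in groups]
    sizes = [a.size for a in arrays]
    fp = None
    if not paired and max(sizes) <= 7 and len(arrays) == 2:
        fp = f_test_var(arrays[0], arrays[1]).p_value
    plan = choose_test(sizes, paired=paired, n_groups=len(arrays),
                       variance_f_test_p=fp, alpha_var=alpha_var)
    if plan.test == "signed_rank":
        result = signed_rank(arrays[0], arrays[1]) if len(arrays) == 2 else signed_rank(arrays[0])
    elif plan.test == "kruskal_dunn":
        result = kruskal_dunn(arrays)
    elif plan.test == "ranksum":
        result = ranksum(arrays[0], arrays[1])
    else:
        result = t_test(arrays[0], arrays[1], welch=plan.test == "t_welch")
    return plan, result


def _split_xy(points):
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y)")
    return arr[:, 0], arr[:, 1]


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)
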