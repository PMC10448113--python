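"""Shared statistical testing.

All group comparisons in the pipeline funnel through this module:
Shapiro-Wilk normality screening, Kruskal-Wallis omnibus testing for more
than two groups with Dunn's post-hoc pairwise z-tests under Bonferroni
correction, Mann-Whitney U for two groups, and the OLS slope test
(H0: regression slope = 0) for trend analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm


@dataclass(frozen=True)
class TestResult:
    __test__ = False          # keep pytest from collecting this dataclass

    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    adjustment: str = "none"
    groups: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def stars(self) -> str:
        """Figure-style significance markers (* p<=0.05 ... *** p<=0.001)."""
        for stars, cut in (("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
            if self.p_value <= cut:
                return stars
        return "ns"

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": float(self.statistic),
                "p_value": float(self.p_value), "group_sizes": list(self.group_sizes),
                "adjustment": self.adjustment, "groups": list(self.groups),
                **{k: v for k, v in self.extra.items()}}


def _as_arrays(groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float) for g in groups]


def normality(sample) -> TestResult:
    """Shapiro-Wilk test of the normality of one sample."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    stat, p = sps.shapiro(x)
    return TestResult("shapiro-wilk", stat, p, (x.size,))


def omnibus_kw(groups, names=None) -> TestResult:
    """Kruskal-Wallis H test across two or more groups."""
    arrays = _as_arrays(groups)
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    stat, p = sps.kruskal(*arrays)
    return TestResult("kruskal-wallis", stat, p, tuple(a.size for a in arrays),
                      groups=tuple(names or ()))


def posthoc_dunn(groups, names=None) -> list[TestResult]:
    """Dunn's pairwise z-tests on pooled ranks, Bonferroni-adjusted.

    Uses the tie-corrected variance of the rank-mean difference; adjusted
    p = min(1, raw * number of comparisons).
    """
    arrays = _as_arrays(groups)
    k = len(arrays)
    if k < 2:
        raise ValueError("post-hoc comparison needs at least 2 groups")
    names = list(names) if names else [str(i) for i in range(k)]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term: sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    splits = np.cumsum([a.size for a in arrays])[:-1]
    rank_groups = np.split(ranks, splits)
    rank_means = [rg.mean() for rg in rank_groups]
    m = k * (k - 1) // 2
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = arrays[i].size, arrays[j].size
            var = (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) * (1 / ni + 1 / nj)
            z = (rank_means[i] - rank_means[j]) / np.sqrt(var)
            raw = 2.0 * sps.norm.sf(abs(z))
            adj = min(1.0, raw * m)
            results.append(TestResult(
                "dunn", z, adj, (ni, nj), adjustment="bonferroni",
                groups=(names[i], names[j]), extra={"p_raw": raw}))
    return results


def two_group(a, b, names=("a", "b")) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for group sizes up to 8 (when no ties cross the
    groups), normal approximation with tie correction otherwise.
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group in two-group comparison")
    method = "exact" if (x.size <= 8 and y.size <= 8
                         and np.unique(np.concatenate([x, y])).size == x.size + y.size) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann-whitney-u", res.statistic, res.pvalue,
                      (x.size, y.size), groups=tuple(names),
                      extra={"method": method})


def ols_slope_test(x, y) -> TestResult:
    """OLS regression of y on x with the two-sided slope-equals-zero test.

    ``extra`` carries slope, intercept and R-squared.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    p = float(model.pvalues[1])
    return TestResult("ols-slope", float(model.tvalues[1]), p, (x.size,),
                      extra={"slope": slope, "intercept": float(model.params[0]),
                             "r_squared": float(model.rsquared)})
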