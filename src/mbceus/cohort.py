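"""Tumor-volume arithmetic, group summaries and nonparametric tests.

Cohort endpoints (volumes, dTE, elasticity ratios, non-enhanced
percentages) are summarized as median (range) and compared with
rank-based tests: Mann-Whitney between two groups, Kruskal-Wallis
across three, Wilcoxon signed rank within a group over time, Spearman
for correlations.  Percentage changes are computed per animal
(``100 (final - start)/start``) and then summarized — the median of
per-animal deltas, which is not the delta of group medians.

Exact small-sample p-values are computed from the permutation null over
the observed multiset (so ties are handled exactly); asymptotic
tie-corrected approximations cover larger samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "TumorMeasurement",
    "ChangeRecord",
    "GroupSummary",
    "TestResult",
    "tumor_volume",
    "percent_delta",
    "fold_change",
    "group_summary",
    "kruskal_wallis",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "spearman",
]

#: Largest per-group size for which the exact Mann-Whitney null is computed.
EXACT_MW_MAX_N = 30
#: Largest number of non-zero pairs for the exact signed-rank null.
EXACT_WILCOXON_MAX_N = 15
#: Largest sample for the exact Spearman permutation null.
EXACT_SPEARMAN_MAX_N = 8


def tumor_volume(height: float, width: float, thickness: float) -> float:
    """Half-ellipsoid volume ``h * w * t / 2`` (mm^3), symmetric in its axes."""
    if min(height, width, thickness) <= 0:
        raise ParameterError("all diameters must be positive")
    return height * width * thickness / 2.0


def percent_delta(start: float, final: float) -> float:
    """Signed percentage change ``100 (final - start) / start``."""
    if start <= 0:
        raise ParameterError("starting value must be positive")
    return 100.0 * (final - start) / start


def fold_change(delta_percent: float) -> float:
    """Fold change implied by a percentage delta: ``1 + delta/100``."""
    if delta_percent <= -100:
        raise ParameterError("a fold change requires delta > -100 %")
    return 1.0 + delta_percent / 100.0


@dataclass(frozen=True)
class TumorMeasurement:
    """One ultrasound size reading (mm) and its implied volume (mm^3)."""

    height: float
    width: float
    thickness: float

    @property
    def volume(self) -> float:
        return tumor_volume(self.height, self.width, self.thickness)


@dataclass(frozen=True)
class ChangeRecord:
    """Start/final pair with its percentage delta and fold change."""

    start_value: float
    final_value: float

    @property
    def delta_percent(self) -> float:
        return percent_delta(self.start_value, self.final_value)

    @property
    def fold(self) -> float:
        return fold_change(self.delta_percent)


@dataclass(frozen=True)
class GroupSummary:
    """Median (range) summary of one endpoint in one group."""

    n: int
    median: float
    range_low: float
    range_high: float


def group_summary(values) -> GroupSummary:
    """Sample median (mean of middle two for even n) with min-max range."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ParameterError("cannot summarize an empty group")
    return GroupSummary(int(v.size), float(np.median(v)), float(v.min()), float(v.max()))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    tie_corrected: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ParameterError("p-value must lie in [0, 1]")


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square(k-1) p-value.

    All-identical data yield H = 0, p = 1 by convention.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ParameterError("need at least two non-empty groups")
    if sum(g.size for g in groups) < 3:
        raise ParameterError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal-wallis")


def _mw_u(a: np.ndarray, b: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([a, b]))
    n = len(a)
    return float(ranks[:n].sum() - n * (n + 1) / 2.0)


def _exact_mw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p from the permutation null over the pooled multiset.

    Counts size-n subsets of the pooled midranks by their (doubled, hence
    integer) rank sum with a subset-sum DP, then sums the probability of
    U at least as far from its null center as observed.
    """
    n, m = len(a), len(b)
    ranks2 = np.rint(2 * sps.rankdata(np.concatenate([a, b]))).astype(int)
    total = ranks2.sum()
    # dp[k][s] = number of size-k subsets with doubled-rank sum s
    dp = np.zeros((n + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        # k descending so each pooled element enters a subset at most once
        for k in range(n, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n]
    u_obs = _mw_u(a, b)
    center = n * m / 2.0
    dev_obs = abs(u_obs - center)
    sums2 = np.arange(total + 1)
    u_all = sums2 / 2.0 - n * (n + 1) / 2.0
    extreme = np.abs(u_all - center) >= dev_obs - 1e-9
    return float(counts[extreme].sum() / comb(n + m, n))


def mann_whitney(a, b, mode: str = "auto", continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='exact'`` enumerates the permutation null over the observed
    multiset (ties handled exactly); ``'asymptotic'`` uses the normal
    approximation with tie-corrected variance.  ``'auto'`` picks exact
    for group sizes up to 10, matching the study's scale.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if max(a.size, b.size) <= 10 else "asymptotic"
    u = _mw_u(a, b)
    if mode == "exact":
        if max(a.size, b.size) > EXACT_MW_MAX_N:
            raise ParameterError(
                f"group sizes above {EXACT_MW_MAX_N} are infeasible for the exact "
                "null; use mode='asymptotic'"
            )
        return TestResult(u, _exact_mw_p(a, b), "mann-whitney-exact")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=continuity
    )
    return TestResult(u, float(res.pvalue), "mann-whitney-asymptotic")


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (all-zero pairs give p = 1 by
    convention); the exact sign-flip null is enumerated for up to 15
    non-zero pairs, beyond that the normal approximation is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, 1.0, "wilcoxon-exact")
    if d.size < 3:
        raise ParameterError("need at least 3 non-zero paired differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    center = n * (n + 1) / 4.0
    if n <= EXACT_WILCOXON_MAX_N:
        # enumerate all 2^n sign assignments of the observed |d| ranks
        signs = np.arange(2**n)[:, None] >> np.arange(n) & 1
        w_all = signs @ ranks
        dev_obs = abs(w_plus - center)
        p = float(np.mean(np.abs(w_all - center) >= dev_obs - 1e-9))
        return TestResult(w_plus, p, "wilcoxon-exact")
    res = sps.wilcoxon(x, y, method="asymptotic")
    return TestResult(w_plus, float(res.pvalue), "wilcoxon-asymptotic")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with midrank ties.

    The p-value is an exact permutation enumeration for n <= 8 and the
    t-approximation otherwise.  Zero rank variance in either variable is
    an error (the correlation is undefined).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("need paired samples of equal length >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ParameterError("zero variance in ranks: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= EXACT_SPEARMAN_MAX_N:
        from itertools import permutations

        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        count = total = 0
        for perm in permutations(range(n)):
            r = float((rxc * ryc[list(perm)]).sum()) / denom
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return TestResult(rho, count / total, "spearman-exact")
    res = sps.spearmanr(x, y)
    return TestResult(rho, float(res.pvalue), "spearman-t")
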