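"""Paired nonparametric tests and proportion confidence intervals.

The Wilcoxon matched-pairs signed-rank test uses the large-sample normal
approximation without continuity correction; zero differences are dropped and
tied absolute differences receive mid-ranks.  The Friedman test uses the
chi-square approximation on within-row mid-ranks.  Strata with too few usable
pairs yield a *skipped* result rather than an error, matching how sparse
strata are reported as "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata

from hrgap.domain import ValidationError


@dataclass(frozen=True)
class TestResult:
    method: str
    n: int
    statistic: float | None
    p_value: float | None
    skipped: bool = False
    skip_reason: str | None = None


@dataclass(frozen=True)
class ProportionCI:
    count: int
    total: int
    point: float  # percent
    lower: float  # percent
    upper: float  # percent
    level: float = 0.95

    @property
    def rounded(self) -> tuple[int, int, int]:
        """(point, lower, upper) rounded half-up to whole percentages."""
        return (
            int(math.floor(self.point + 0.5)),
            int(math.floor(self.lower + 0.5)),
            int(math.floor(self.upper + 0.5)),
        )


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on (available, ideal) pairs.

    W is the smaller of the positive- and negative-rank sums;
    z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24), p = 2 * Phi(z).
    """
    diffs = np.asarray([a - b for a, b in pairs], dtype=float)
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n < 2:
        reason = (
            "all differences zero" if len(pairs) and n == 0 else "fewer than 2 usable pairs"
        )
        return TestResult("wilcoxon_signed_rank", n, None, None, True, reason)
    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    w = min(w_plus, w_minus)
    mean = n * (n + 1) / 4.0
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w - mean) / sd
    p = min(1.0, 2.0 * norm.cdf(z))
    return TestResult("wilcoxon_signed_rank", n, w, p)


def wilcoxon_exact_p(pairs: Sequence[tuple[float, float]]) -> float:
    """Exact two-sided p by enumerating all sign assignments (oracle; n <= ~16)."""
    diffs = np.asarray([a - b for a, b in pairs], dtype=float)
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n < 1:
        raise ValidationError("no nonzero differences")
    if n > 16:
        raise ValidationError("exact enumeration limited to n <= 16")
    ranks = rankdata(np.abs(diffs))
    w_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
    total = ranks.sum()
    count = 0
    for mask in range(1 << n):
        w_plus = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if min(w_plus, total - w_plus) <= w_obs + 1e-12:
            count += 1
    return count / (1 << n)


def friedman_test(
    columns: Sequence[Sequence[float]] | np.ndarray,
) -> TestResult:
    """Friedman chi-square test on k related columns (facilities as rows).

    Within-row mid-ranks; chi2_F = 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1),
    referred to chi-square with k-1 degrees of freedom.
    """
    data = np.asarray(columns, dtype=float).T  # rows = subjects
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValidationError("friedman_test needs k >= 2 related columns")
    n, k = data.shape
    if n < 2:
        return TestResult("friedman", n, None, None, True, "fewer than 2 rows")
    ranks = np.apply_along_axis(rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)
    p = float(chi2.sf(stat, k - 1))
    return TestResult("friedman", n, stat, p)


def friedman_permutation_p(
    columns: Sequence[Sequence[float]] | np.ndarray,
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation-null p for the Friedman statistic (oracle): within-row shuffles."""
    data = np.asarray(columns, dtype=float).T
    n, k = data.shape
    rng = np.random.default_rng(seed)

    def stat_of(d: np.ndarray) -> float:
        ranks = np.apply_along_axis(rankdata, 1, d)
        rs = ranks.sum(axis=0)
        return 12.0 / (n * k * (k + 1)) * float((rs**2).sum()) - 3.0 * n * (k + 1)

    observed = stat_of(data)
    hits = 0
    for _ in range(n_draws):
        shuffled = np.array([rng.permutation(row) for row in data])
        if stat_of(shuffled) >= observed - 1e-12:
            hits += 1
    return hits / n_draws


def proportion_ci(count: int, total: int, level: float = 0.95) -> ProportionCI:
    """Wald normal-approximation interval on the percentage scale, clipped to [0, 100]."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= count <= total:
        raise ValidationError(f"count must be in [0, {total}], got {count}")
    p = count / total
    z = norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(p * (1.0 - p) / total)
    point = 100.0 * p
    half = 100.0 * z * se
    return ProportionCI(
        count=count,
        total=total,
        point=point,
        lower=max(0.0, point - half),
        upper=min(100.0, point + half),
        level=level,
    )
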