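import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrgap.domain import ValidationError
from hrgap.stats import (
    friedman_test,
    proportion_ci,
    wilcoxon_exact_p,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(diffs):
    """Independent oracle: exact two-sided p over all 2^n sign assignments."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    absd = [abs(d) for d in diffs]
    ranks = [
        sum(1 for b in absd if b < a) + (1 + sum(1 for b in absd if b == a)) / 2
        for a in absd
    ]
    total = sum(ranks)
    w_obs = min(
        sum(r for r, d in zip(ranks, diffs) if d > 0),
        sum(r for r, d in zip(ranks, diffs) if d < 0),
    )
    hits = 0
    for signs in itertools.product((1, -1), repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
        if min(w_plus, total - w_plus) <= w_obs + 1e-12:
            hits += 1
    return hits / 2**n


class TestWilcoxon:
    def test_w0_n12_matches_printed_p(self):
        # 12 pairs, every facility short -> W = 0
        pairs = [(i, i + 1 + 0.1 * i) for i in range(12)]
        result = wilcoxon_signed_rank(pairs)
        assert result.statistic == 0
        assert result.p_value == pytest.approx(0.0022, abs=5e-5)

    def test_w1_n12(self):
        # one pair against the trend with the smallest rank
        diffs = [-(i + 2.0) for i in range(11)] + [1.0]
        pairs = [(d, 0.0) for d in diffs]
        result = wilcoxon_signed_rank(pairs)
        assert result.statistic == 1
        assert result.p_value == pytest.approx(0.0029, abs=5e-5)

    def test_all_identical_skipped(self):
        result = wilcoxon_signed_rank([(3.0, 3.0)] * 6)
        assert result.skipped
        assert result.p_value is None
        assert "zero" in result.skip_reason

    def test_single_usable_pair_skipped(self):
        assert wilcoxon_signed_rank([(1.0, 2.0)]).skipped

    def test_zero_differences_dropped(self):
        pairs = [(1.0, 2.0), (2.0, 4.0), (5.0, 5.0), (3.0, 7.0)]
        assert wilcoxon_signed_rank(pairs).n == 3

    @staticmethod
    def _diffs_with_positive_rank_sum(n, w):
        """Signed ranks 1..n whose positive-rank sum is exactly w (greedy)."""
        positive = set()
        remaining = w
        for r in range(n, 0, -1):
            if r <= remaining:
                positive.add(r)
                remaining -= r
        assert remaining == 0
        return [float(r) if r in positive else -float(r) for r in range(1, n + 1)]

    @pytest.mark.parametrize("n", range(5, 13))
    def test_normal_approximation_close_to_exact_in_tail(self, n):
        # Exhaustive over every achievable W whose exact p is in the
        # decision-relevant tail (<= 0.1): agreement within 0.02 throughout.
        checked = 0
        for w in range(n * (n + 1) // 4 + 1):
            diffs = self._diffs_with_positive_rank_sum(n, w)
            exact = brute_force_wilcoxon_p(diffs)
            if exact > 0.1:
                break
            approx = wilcoxon_signed_rank([(d, 0.0) for d in diffs]).p_value
            assert abs(approx - exact) <= 0.02
            checked += 1
        assert checked >= 1  # n = 5 has a single tail point (W = 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_package_exact_oracle_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.normal(0.2, 1.0, size=7)
        pairs = [(d, 0.0) for d in diffs]
        assert wilcoxon_exact_p(pairs) == pytest.approx(brute_force_wilcoxon_p(diffs))

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=100),
                st.floats(min_value=0, max_value=100),
            ),
            min_size=2,
            max_size=15,
        )
    )
    @settings(max_examples=50)
    def test_sign_flip_invariance(self, pairs):
        forward = wilcoxon_signed_rank(pairs)
        flipped = wilcoxon_signed_rank([(b, a) for a, b in pairs])
        assert forward.skipped == flipped.skipped
        if not forward.skipped:
            assert forward.p_value == pytest.approx(flipped.p_value)
            assert forward.statistic == pytest.approx(flipped.statistic)


def friedman_statistic_oracle(data):
    """Independent statistic via argsort ranks (no ties in the inputs used)."""
    n, k = data.shape
    ranks = np.empty_like(data)
    for i, row in enumerate(data):
        order = np.argsort(row)
        ranks[i, order] = np.arange(1, k + 1)
    rank_sums = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3.0 * n * (k + 1)


class TestFriedman:
    def test_identical_columns(self):
        col = [1.0, 2.0, 3.0, 4.0]
        result = friedman_test([col, col, col])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_strict_ordering_hits_closed_form_bound(self):
        n = 12
        a = [float(i) for i in range(n)]
        b = [x + 1 for x in a]
        c = [x + 2 for x in a]
        result = friedman_test([a, b, c])
        assert result.statistic == pytest.approx(2 * n)  # rank sums 12, 24, 36
        assert result.p_value < 1e-4

    def test_statistic_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(9, 3))
        result = friedman_test(data.T)
        assert result.statistic == pytest.approx(friedman_statistic_oracle(data))

    def test_p_close_to_permutation_null(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(6, 3))
        data[:, 2] += 1.0
        result = friedman_test(data.T)
        observed = result.statistic
        draws = 10_000
        hits = 0
        perm_rng = np.random.default_rng(99)
        for _ in range(draws):
            shuffled = np.array([perm_rng.permutation(row) for row in data])
            if friedman_statistic_oracle(shuffled) >= observed - 1e-12:
                hits += 1
        assert abs(result.p_value - hits / draws) <= 0.05

    def test_monotone_row_transform_invariance(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(1, 10, size=(8, 3))
        base = friedman_test(data.T)
        transformed = friedman_test(np.exp(data).T)
        assert base.statistic == pytest.approx(transformed.statistic)

    def test_too_few_rows_skipped(self):
        result = friedman_test([[1.0], [2.0], [3.0]])
        assert result.skipped

    def test_needs_at_least_two_columns(self):
        with pytest.raises(ValidationError):
            friedman_test([[1.0, 2.0]])


class TestProportionCI:
    def test_service_delivery_share(self):
        ci = proportion_ci(489, 866)
        _, lower, upper = ci.rounded
        assert (lower, upper) == (53, 60)

    def test_clipping_at_zero(self):
        ci = proportion_ci(0, 100)
        assert ci.lower == 0.0
        assert ci.point == 0.0

    def test_hand_arithmetic(self):
        ci = proportion_ci(250, 1000)
        assert ci.lower == pytest.approx(22.3, abs=0.05)
        assert ci.upper == pytest.approx(27.7, abs=0.05)

    def test_width_shrinks_like_root_n(self):
        narrow = proportion_ci(400, 1600)
        wide = proportion_ci(100, 400)
        ratio = (wide.upper - wide.lower) / (narrow.upper - narrow.lower)
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            proportion_ci(0, 0)

    def test_count_bounds(self):
        with pytest.raises(ValidationError):
            proportion_ci(11, 10)

    @given(st.integers(min_value=0, max_value=500), st.integers(min_value=1, max_value=500))
    def test_bounds_ordered(self, count, total):
        if count > total:
            count = total
        ci = proportion_ci(count, total)
        assert 0.0 <= ci.lower <= ci.upper <= 100.0
        assert ci.lower <= ci.point + 1e-9
        assert ci.point <= ci.upper + 1e-9
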