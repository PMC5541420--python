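import statistics

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hrgap import calibration as calib
from hrgap.domain import (
    ActivityAssignment,
    AgeGroup,
    Cadre,
    EstimationConfig,
    FacilityProfile,
    TimeEstimate,
    ValidationError,
    activities_to_group_minutes,
    aggregate_median,
    available_supply_hours,
    hours_to_fte,
    ideal_supply_hours,
    median_time_difference,
    round_half_up,
    summarize_times,
    supply_gap,
)

PHYSICIAN_AVAILABLE = [s.available for s in calib.PHYSICIAN_STAFFING]


class TestAvailableSupply:
    def test_ten_workers(self):
        assert available_supply_hours(10) == 12_000

    def test_zero_workers(self):
        assert available_supply_hours(0) == 0

    def test_urban_physician_total(self):
        urban = [s for s in calib.PHYSICIAN_STAFFING if s.locality == "urban"]
        headcount = int(sum(s.available for s in urban))
        assert headcount == 118
        assert available_supply_hours(headcount) == 141_600

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            available_supply_hours(-1)

    def test_utilization_scales(self):
        config = EstimationConfig(utilization=0.5)
        assert available_supply_hours(10, config) == 6_000


class TestIdealSupply:
    def test_one_hour_per_person(self):
        times = [TimeEstimate("f", "g", Cadre.PHYSICIAN, 60.0, 60.0)]
        hours = ideal_supply_hours(times, {"g": 1_200})
        assert hours.tu == pytest.approx(1_200)

    def test_hand_arithmetic(self):
        times = [TimeEstimate("f", "g", Cadre.PHYSICIAN, 73.0, 73.0)]
        hours = ideal_supply_hours(times, {"g": 268_527})
        assert hours.tu == pytest.approx(326_707.85)

    def test_zero_population(self):
        times = [TimeEstimate("f", "g", Cadre.NURSE, 30.0, 40.0)]
        assert ideal_supply_hours(times, {"g": 0}) == (0.0, 0.0)

    def test_missing_population_entry(self):
        times = [TimeEstimate("f", "g", Cadre.NURSE, 30.0, 40.0)]
        with pytest.raises(ValidationError, match="no population entry"):
            ideal_supply_hours(times, {"other": 10})

    def test_channels_are_separate(self):
        times = [TimeEstimate("f", "g", Cadre.NURSE, 30.0, 45.0)]
        hours = ideal_supply_hours(times, {"g": 120})
        assert hours.tu == pytest.approx(60.0)
        assert hours.tr == pytest.approx(90.0)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_linear_in_population(self, n):
        times = [
            TimeEstimate("f", "a", Cadre.PHYSICIAN, 12.5, 20.0),
            TimeEstimate("f", "b", Cadre.PHYSICIAN, 7.0, 9.0),
        ]
        single = ideal_supply_hours(times, {"a": n, "b": 2 * n})
        double = ideal_supply_hours(times, {"a": 2 * n, "b": 4 * n})
        assert double.tu == pytest.approx(2 * single.tu)
        assert double.tr == pytest.approx(2 * single.tr)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=200),
                st.floats(min_value=0, max_value=200),
                st.integers(min_value=0, max_value=5_000),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_required_channel_dominates_when_tr_exceeds_tu(self, rows):
        times = [
            TimeEstimate("f", f"g{i}", Cadre.NURSE, tu, tu + extra)
            for i, (tu, extra, _) in enumerate(rows)
        ]
        population = {f"g{i}": pop for i, (_, _, pop) in enumerate(rows)}
        hours = ideal_supply_hours(times, population)
        assert hours.tr >= hours.tu - 1e-9


class TestFTE:
    def test_examples(self):
        assert hours_to_fte(12_000) == 10.0
        assert hours_to_fte(0) == 0.0

    def test_urban_hp_ideal(self):
        fte = hours_to_fte(16_749.0)
        assert fte == pytest.approx(13.9575)
        assert round_half_up(fte, 1) == 14.0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            hours_to_fte(-1.0)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_round_trip(self, n):
        assert hours_to_fte(available_supply_hours(n)) == n


class TestGap:
    def test_urban_physician(self):
        assert supply_gap(12_000, 22_624.2) == pytest.approx(-10_624.2)

    def test_rural_physician(self):
        assert supply_gap(1_800, 4_079.7) == pytest.approx(-2_279.7)

    @given(st.floats(min_value=0, max_value=1e9))
    def test_identity(self, x):
        assert supply_gap(x, x) == 0


class TestMedian:
    def test_physician_available_column(self):
        assert aggregate_median(PHYSICIAN_AVAILABLE) == 5.0

    def test_singleton(self):
        assert aggregate_median([42]) == 42

    def test_even_rule(self):
        assert aggregate_median([1, 2, 3, 4]) == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_median([])

    @given(st.lists(st.floats(allow_nan=False, allow_infinity=False, width=32), min_size=1, max_size=25))
    def test_against_stdlib_oracle(self, values):
        assert aggregate_median(values) == pytest.approx(statistics.median(values))


class TestTimeDifference:
    @pytest.mark.parametrize(
        "used, required, expected",
        [(73.00, 105.00, -32.00), (55.50, 90.00, -34.50), (7.25, 7.25, 0.0)],
    )
    def test_examples(self, used, required, expected):
        assert median_time_difference(used, required) == pytest.approx(expected)


class TestCanonicalFixture:
    def test_activities_sum_to_99(self):
        assert sum(g.group.n_activities for g in calib.CANONICAL_GROUPS) == 99

    def test_population_sums(self):
        assert sum(g.population for g in calib.CANONICAL_GROUPS) == 268_527
        assert calib.URBAN_POPULATION + calib.RURAL_POPULATION == calib.TOTAL_POPULATION


class TestTypes:
    def test_age_group_rejects_negative_activities(self):
        with pytest.raises(ValidationError):
            AgeGroup("x", "X", -1)

    def test_facility_rejects_bad_locality(self):
        with pytest.raises(ValidationError, match="locality"):
            FacilityProfile("f", "s", "periurban", {}, {})

    def test_facility_rejects_negative_headcount(self):
        with pytest.raises(ValidationError):
            FacilityProfile("f", "s", "urban", {Cadre.NURSE: -2}, {})

    def test_time_estimate_rejects_negative(self):
        with pytest.raises(ValidationError):
            TimeEstimate("f", "g", Cadre.NURSE, -1.0, 0.0)

    def test_config_defaults_consistent(self):
        config = EstimationConfig()
        assert config.working_days_per_year * config.hours_per_day == config.annual_fte_hours

    def test_config_rejects_nonpositive(self):
        with pytest.raises(Exception):
            EstimationConfig(annual_fte_hours=0)


class TestActivityReduction:
    def test_sums_per_group_and_cadre(self):
        acts = [
            ActivityAssignment("a1", "g", Cadre.NURSE, 5.0, 8.0),
            ActivityAssignment("a2", "g", Cadre.NURSE, 3.0, 4.0),
            ActivityAssignment("a3", "g", Cadre.PHYSICIAN, 2.0, 2.0),
        ]
        totals = activities_to_group_minutes(acts)
        assert totals[("g", Cadre.NURSE)] == (8.0, 12.0)
        assert totals[("g", Cadre.PHYSICIAN)] == (2.0, 2.0)

    def test_duplicate_activity_id_rejected(self):
        acts = [
            ActivityAssignment("a1", "g", Cadre.NURSE, 5.0, 8.0),
            ActivityAssignment("a1", "g", Cadre.PHYSICIAN, 3.0, 4.0),
        ]
        with pytest.raises(ValidationError, match="duplicate"):
            activities_to_group_minutes(acts)


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [(13.75, 1, 13.8), (13.74, 1, 13.7), (0.05, 1, 0.1), (56.466, 0, 56.0), (-8.85, 1, -8.9)],
    )
    def test_half_up(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected


class TestTimeSummary:
    def test_canonical_total_is_median_of_cadre_sums(self):
        times = [
            TimeEstimate("f1", "g", Cadre.PHYSICIAN, 10.0, 20.0),
            TimeEstimate("f1", "g", Cadre.NURSE, 5.0, 10.0),
            TimeEstimate("f2", "g", Cadre.PHYSICIAN, 30.0, 40.0),
            TimeEstimate("f2", "g", Cadre.NURSE, 10.0, 20.0),
            TimeEstimate("f3", "g", Cadre.PHYSICIAN, 20.0, 25.0),
            TimeEstimate("f3", "g", Cadre.NURSE, 20.0, 30.0),
        ]
        summary = summarize_times(times, stratum="g")
        # facility sums: 15, 40, 40 -> median 40; cadre medians 20 + 10 + 0
        assert summary.used_total == 40.0
        assert summary.used_total_of_medians == 30.0
        assert summary.diff_total == summary.used_total - summary.required_total

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_times([])
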