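"""Data model and deterministic supply/gap arithmetic.

The estimation chain is:

1. available supply  ``As = headcount x working_days x hours_per_day``  (annual hours)
2. ideal supply      ``Is = sum_groups per-person annual minutes x attended population / 60``
3. FTE conversion    ``FTE = annual hours / annual_fte_hours``
4. gap               ``As - Is`` (negative means shortage)

Two ideal-supply channels are carried throughout: one from *time used* (``tu``,
minutes staff actually spend per person per year) and one from *time required*
(``tr``, minutes staff deem suitable).  All summaries of the skewed time data
are medians.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

from pydantic import BaseModel, Field, model_validator


class ValidationError(ValueError):
    """Raised when an input violates a domain precondition."""


class Cadre(str, enum.Enum):
    """Occupational categories; each package activity maps to exactly one."""

    PHYSICIAN = "physician"
    NURSE = "nurse"
    HEALTH_PROMOTER = "health_promoter"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Cadres that deliver the prevention/promotion package.
SERVICE_CADRES: tuple[Cadre, ...] = (
    Cadre.PHYSICIAN,
    Cadre.NURSE,
    Cadre.HEALTH_PROMOTER,
)

LOCALITIES = ("urban", "rural")


@dataclass(frozen=True)
class AgeGroup:
    """A demand age/service group with its share of package activities."""

    id: str
    label: str
    n_activities: int

    def __post_init__(self) -> None:
        if self.n_activities < 0:
            raise ValidationError(f"n_activities must be >= 0, got {self.n_activities}")


@dataclass(frozen=True)
class ActivityAssignment:
    """One package activity assigned to a single cadre, with per-person annual minutes."""

    activity_id: str
    age_group: str
    cadre: Cadre
    annual_minutes_used: float
    annual_minutes_required: float

    def __post_init__(self) -> None:
        if self.annual_minutes_used < 0 or self.annual_minutes_required < 0:
            raise ValidationError(
                f"activity {self.activity_id}: minutes must be non-negative"
            )


@dataclass(frozen=True)
class FacilityProfile:
    """One facility: locality class, cadre headcounts, attended population by age group."""

    facility_id: str
    state: str
    locality: str
    headcount: Mapping[Cadre, int]
    population: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.locality not in LOCALITIES:
            raise ValidationError(
                f"facility {self.facility_id}: locality must be one of {LOCALITIES}, "
                f"got {self.locality!r}"
            )
        for cadre, n in self.headcount.items():
            if int(n) != n or n < 0:
                raise ValidationError(
                    f"facility {self.facility_id}: headcount[{cadre}] must be a "
                    f"non-negative integer, got {n!r}"
                )
        for group, n in self.population.items():
            if int(n) != n or n < 0:
                raise ValidationError(
                    f"facility {self.facility_id}: population[{group}] must be a "
                    f"non-negative integer, got {n!r}"
                )

    @property
    def total_population(self) -> int:
        return int(sum(self.population.values()))


@dataclass(frozen=True)
class TimeEstimate:
    """Per facility x age group x cadre annual per-person minutes, used and required."""

    facility_id: str
    age_group: str
    cadre: Cadre
    tu: float
    tr: float

    def __post_init__(self) -> None:
        if self.tu < 0 or self.tr < 0:
            raise ValidationError(
                f"facility {self.facility_id}, group {self.age_group}: "
                "times must be non-negative"
            )


class EstimationConfig(BaseModel):
    """Working-time accounting constants.

    Defaults: 200 working days/year x 6 h/day = 1200 annual FTE hours.
    ``utilization`` (default 1.0) optionally scales available hours when not
    all working time is attributable to package delivery.
    """

    working_days_per_year: float = Field(default=200, gt=0)
    hours_per_day: float = Field(default=6, gt=0)
    annual_fte_hours: float = Field(default=1200, gt=0)
    utilization: float = Field(default=1.0, gt=0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "EstimationConfig":
        return self


class IdealHours(NamedTuple):
    """Annual ideal-supply hours for the two time channels."""

    tu: float
    tr: float


@dataclass(frozen=True)
class SupplyEstimate:
    """Available and ideal annual hours for one facility (or stratum) x cadre."""

    facility_id: str
    cadre: Cadre
    as_hours: float
    is_tu_hours: float
    is_tr_hours: float

    def __post_init__(self) -> None:
        if self.as_hours < 0 or self.is_tu_hours < 0 or self.is_tr_hours < 0:
            raise ValidationError("supply hours must be non-negative")

    @property
    def gap_tu_hours(self) -> float:
        return supply_gap(self.as_hours, self.is_tu_hours)

    @property
    def gap_tr_hours(self) -> float:
        return supply_gap(self.as_hours, self.is_tr_hours)


@dataclass(frozen=True)
class FTEGap:
    """Supply expressed as (possibly fractional) worker counts, with gaps."""

    cadre: Cadre
    stratum: str
    available_fte: float
    ideal_fte_tu: float
    ideal_fte_tr: float
    gap_tu: float = field(init=False)
    gap_tr: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gap_tu", self.available_fte - self.ideal_fte_tu)
        object.__setattr__(self, "gap_tr", self.available_fte - self.ideal_fte_tr)


@dataclass(frozen=True)
class TimeSummary:
    """Median per-person minutes for one stratum, split by cadre.

    ``total`` is the canonical total: the median of per-observation cadre-summed
    minutes.  ``total_of_medians`` is the alternative aggregation (sum of the
    per-cadre medians); medians are not additive so the two generally differ.
    """

    stratum: str
    used_total: float
    used_physician: float
    used_nurse: float
    used_hp: float
    required_total: float
    required_physician: float
    required_nurse: float
    required_hp: float
    used_total_of_medians: float
    required_total_of_medians: float

    @property
    def diff_total(self) -> float:
        return median_time_difference(self.used_total, self.required_total)

    @property
    def diff_physician(self) -> float:
        return median_time_difference(self.used_physician, self.required_physician)

    @property
    def diff_nurse(self) -> float:
        return median_time_difference(self.used_nurse, self.required_nurse)

    @property
    def diff_hp(self) -> float:
        return median_time_difference(self.used_hp, self.required_hp)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def available_supply_hours(
    headcount: int, config: EstimationConfig | None = None
) -> float:
    """Annual hours available from ``headcount`` contracted workers.

    ``headcount x working_days_per_year x hours_per_day x utilization``.
    """
    config = config or EstimationConfig()
    if headcount < 0:
        raise ValidationError(f"headcount must be non-negative, got {headcount}")
    return (
        headcount
        * config.working_days_per_year
        * config.hours_per_day
        * config.utilization
    )


def ideal_supply_hours(
    times: Iterable[TimeEstimate], population: Mapping[str, int]
) -> IdealHours:
    """Annual hours needed to serve the attended population.

    For each age group: per-person annual minutes x attended population / 60,
    summed over groups.  Computed separately for the time-used and the
    time-required channel.  Every timed group must have a population entry.
    """
    total_tu = 0.0
    total_tr = 0.0
    for t in times:
        if t.age_group not in population:
            raise ValidationError(
                f"facility {t.facility_id}: no population entry for age group "
                f"{t.age_group!r}"
            )
        n = population[t.age_group]
        total_tu += t.tu * n / 60.0
        total_tr += t.tr * n / 60.0
    return IdealHours(tu=total_tu, tr=total_tr)


def hours_to_fte(hours: float, config: EstimationConfig | None = None) -> float:
    """Convert annual hours into full-time-equivalent worker counts."""
    config = config or EstimationConfig()
    if hours < 0:
        raise ValidationError(f"hours must be non-negative, got {hours}")
    return hours / config.annual_fte_hours


def supply_gap(available: float, ideal: float) -> float:
    """Signed difference available - ideal; negative means shortage."""
    return available - ideal


def aggregate_median(values: Sequence[float]) -> float:
    """Median: middle of the sorted values, mean of the two central ones for even n."""
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        raise ValidationError("median of empty sequence")
    mid = n // 2
    if n % 2:
        return float(vals[mid])
    return (vals[mid - 1] + vals[mid]) / 2.0


def median_time_difference(summary_used: float, summary_required: float) -> float:
    """Used-minus-required minutes; negative when required exceeds used."""
    return summary_used - summary_required


def activities_to_group_minutes(
    assignments: Iterable[ActivityAssignment],
) -> dict[tuple[str, Cadre], tuple[float, float]]:
    """Reduce per-activity minutes to (age_group, cadre) annual totals.

    Activity ids must be unique within an age group.  Returns a mapping
    ``(age_group, cadre) -> (minutes_used, minutes_required)``.
    """
    seen: set[tuple[str, str]] = set()
    totals: dict[tuple[str, Cadre], list[float]] = {}
    for a in assignments:
        key = (a.age_group, a.activity_id)
        if key in seen:
            raise ValidationError(
                f"duplicate activity id {a.activity_id!r} in age group {a.age_group!r}"
            )
        seen.add(key)
        acc = totals.setdefault((a.age_group, a.cadre), [0.0, 0.0])
        acc[0] += a.annual_minutes_used
        acc[1] += a.annual_minutes_required
    return {k: (v[0], v[1]) for k, v in totals.items()}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (13.75 -> 13.8), as in tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_times(
    times: Iterable[TimeEstimate], stratum: str = "all"
) -> TimeSummary:
    """Median per-person minutes by cadre over a set of facility x group observations.

    The canonical total is the median of the per-(facility, group) cadre-summed
    minutes; the sum-of-cadre-medians variant is also reported.
    """
    by_obs_tu: dict[tuple[str, str], float] = {}
    by_obs_tr: dict[tuple[str, str], float] = {}
    per_cadre_tu: dict[Cadre, list[float]] = {c: [] for c in SERVICE_CADRES}
    per_cadre_tr: dict[Cadre, list[float]] = {c: [] for c in SERVICE_CADRES}
    for t in times:
        obs = (t.facility_id, t.age_group)
        by_obs_tu[obs] = by_obs_tu.get(obs, 0.0) + t.tu
        by_obs_tr[obs] = by_obs_tr.get(obs, 0.0) + t.tr
        if t.cadre in per_cadre_tu:
            per_cadre_tu[t.cadre].append(t.tu)
            per_cadre_tr[t.cadre].append(t.tr)
    if not by_obs_tu:
        raise ValidationError("no time estimates to summarize")

    def med(values: list[float]) -> float:
        return aggregate_median(values) if values else 0.0

    cadre_med_tu = {c: med(v) for c, v in per_cadre_tu.items()}
    cadre_med_tr = {c: med(v) for c, v in per_cadre_tr.items()}
    return TimeSummary(
        stratum=stratum,
        used_total=aggregate_median(list(by_obs_tu.values())),
        used_physician=cadre_med_tu[Cadre.PHYSICIAN],
        used_nurse=cadre_med_tu[Cadre.NURSE],
        used_hp=cadre_med_tu[Cadre.HEALTH_PROMOTER],
        required_total=aggregate_median(list(by_obs_tr.values())),
        required_physician=cadre_med_tr[Cadre.PHYSICIAN],
        required_nurse=cadre_med_tr[Cadre.NURSE],
        required_hp=cadre_med_tr[Cadre.HEALTH_PROMOTER],
        used_total_of_medians=sum(cadre_med_tu.values()),
        required_total_of_medians=sum(cadre_med_tr.values()),
    )
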