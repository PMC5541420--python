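"""Published reference values for the Mexican prevention/promotion package setting.

These constants calibrate the synthetic-data generator and anchor the
validation suite: the canonical 10 age/service groups of the 99-activity
guaranteed package, the 2009 attended-population distribution, the elicited
median per-person annual service minutes (used and required, by cadre), and
the per-facility staffing/FTE columns of the 20 study facilities.

They are *calibration inputs*, never analysis outputs: every pipeline number
is recomputed from (synthetic or user-supplied) facility data.
"""

from __future__ import annotations

from dataclasses import dataclass

from hrgap.domain import AgeGroup, Cadre


@dataclass(frozen=True)
class GroupCalibration:
    """One age group: activity count, attended population, median minutes."""

    group: AgeGroup
    population: int
    #: median per-person annual minutes used: (total, physician, nurse, hp)
    used: tuple[float, float, float, float]
    #: median per-person annual minutes required: (total, physician, nurse, hp)
    required: tuple[float, float, float, float]


#: Canonical 10 age/service groups; activity counts sum to 99 and attended
#: populations to 268 527.
CANONICAL_GROUPS: tuple[GroupCalibration, ...] = (
    GroupCalibration(
        AgeGroup("newborn", "Newborns", 10),
        5601,
        (55.50, 24.00, 27.00, 5.00),
        (90.00, 41.00, 43.50, 10.00),
    ),
    GroupCalibration(
        AgeGroup("under5", "Children under 5 years", 10),
        41094,
        (61.50, 13.50, 33.50, 15.50),
        (94.00, 20.00, 46.00, 22.50),
    ),
    GroupCalibration(
        AgeGroup("age5to9", "Children from 5 to 9 years", 10),
        24266,
        (71.00, 30.00, 20.00, 14.00),
        (94.50, 40.00, 30.00, 22.50),
    ),
    GroupCalibration(
        AgeGroup("teen", "Teens from 10 to 19 years", 10),
        50508,
        (97.50, 60.00, 17.50, 27.50),
        (131.00, 77.50, 25.00, 35.00),
    ),
    GroupCalibration(
        AgeGroup("women20to59", "Women from 20 to 59 years", 11),
        76839,
        (97.50, 40.00, 25.00, 35.50),
        (165.40, 57.50, 37.50, 76.50),
    ),
    GroupCalibration(
        AgeGroup("men20to59", "Men from 20 to 59 years", 11),
        39459,
        (83.50, 37.50, 32.50, 25.00),
        (152.50, 51.50, 30.00, 62.50),
    ),
    GroupCalibration(
        AgeGroup("over60", "Women and men over 60 years", 10),
        16591,
        (100.00, 52.50, 39.50, 15.00),
        (162.50, 70.00, 72.50, 20.00),
    ),
    GroupCalibration(
        AgeGroup("pregnant_first", "Pregnant women, first visit", 10),
        7610,
        (61.50, 46.00, 10.00, 5.00),
        (85.50, 67.00, 10.00, 9.00),
    ),
    GroupCalibration(
        AgeGroup("pregnant_later", "Pregnant women, subsequent visits", 7),
        5076,
        (46.50, 36.50, 10.00, 0.00),
        (58.50, 47.00, 10.00, 0.00),
    ),
    GroupCalibration(
        AgeGroup("postnatal", "Postnatal care", 10),
        1483,
        (58.50, 27.50, 35.00, 0.00),
        (91.50, 37.00, 50.00, 0.00),
    ),
)

#: Grand medians over all groups: per-person annual minutes (total, phys, nurse, hp).
ALL_GROUPS_USED = (73.00, 40.00, 25.00, 22.00)
ALL_GROUPS_REQUIRED = (105.00, 51.00, 35.00, 30.00)

TOTAL_ACTIVITIES = 99
TOTAL_POPULATION = 268_527
URBAN_POPULATION = 233_618
RURAL_POPULATION = 34_909

#: Workforce composition of the 20 study facilities (2009 head counts).
TOTAL_HEALTH_WORKERS = 866
SERVICE_DELIVERY_WORKERS = 489
ADMINISTRATIVE_WORKERS = 377
SERVICE_DELIVERY_BY_CADRE = {
    "nurse": 220,
    "physician": 176,
    "health_promoter": 39,
    "nutrition_psychology_social_work": 15,
    "dentist_or_student": 39,
}


@dataclass(frozen=True)
class FacilityStaffing:
    """Per-facility FTE columns: available headcount and ideal FTE per channel."""

    name: str
    locality: str
    available: float
    ideal_tu: float
    ideal_tr: float


#: Physician staffing of the 20 study facilities (12 urban, 8 rural):
#: available headcount, ideal FTE from time used, ideal FTE from time required.
PHYSICIAN_STAFFING: tuple[FacilityStaffing, ...] = (
    FacilityStaffing("Tapalpa", "urban", 6.0, 5.5, 8.7),
    FacilityStaffing("Jesus Rosal", "urban", 11.0, 60.6, 108.9),
    FacilityStaffing("Satellite", "urban", 2.0, 3.2, 4.7),
    FacilityStaffing("Coapa", "urban", 10.0, 11.1, 16.1),
    FacilityStaffing("GR. Millan", "urban", 10.0, 15.3, 29.5),
    FacilityStaffing("Zacatecas", "urban", 10.0, 24.8, 30.3),
    FacilityStaffing("W. Escalante", "urban", 10.0, 24.3, 36.0),
    FacilityStaffing("Industrial", "urban", 13.0, 43.2, 48.4),
    FacilityStaffing("Rena II", "urban", 3.0, 4.8, 6.1),
    FacilityStaffing("Pedro Escobedo", "urban", 23.0, 81.0, 119.9),
    FacilityStaffing("Toluca", "urban", 16.0, 22.4, 33.4),
    FacilityStaffing("San Rafael", "urban", 4.0, 13.0, 26.3),
    FacilityStaffing("Juanacatlan", "rural", 2.0, 9.7, 11.4),
    FacilityStaffing("Mineral Chico", "rural", 3.0, 6.8, 10.5),
    FacilityStaffing("Cuentepec", "rural", 4.0, 2.0, 2.9),
    FacilityStaffing("Sta Elena", "rural", 1.0, 2.1, 2.2),
    FacilityStaffing("Koben", "rural", 1.0, 1.4, 2.6),
    FacilityStaffing("G. Victoria", "rural", 12.0, 23.6, 31.8),
    FacilityStaffing("R02 Kilometro 30", "rural", 1.0, 4.3, 5.2),
    FacilityStaffing("P. Coyote", "rural", 1.0, 2.5, 3.9),
)

#: Health-promoter headcounts of the 12 urban facilities (mostly zero).
URBAN_HP_HEADCOUNTS: tuple[int, ...] = (0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 9, 13)

#: Urban nurse headcount total implied by 220 800 available annual hours.
URBAN_NURSE_TOTAL = 184
RURAL_NURSE_TOTAL = 32
RURAL_HP_TOTAL = 1


def canonical_age_groups() -> list[AgeGroup]:
    return [g.group for g in CANONICAL_GROUPS]


def cadre_minutes(
    calibration: GroupCalibration, channel: str
) -> dict[Cadre, float]:
    """Per-cadre median minutes for one group, ``channel`` in {'used', 'required'}."""
    _, phys, nurse, hp = getattr(calibration, channel)
    return {Cadre.PHYSICIAN: phys, Cadre.NURSE: nurse, Cadre.HEALTH_PROMOTER: hp}
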