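"""CSV/YAML readers and writers and input validation.

Canonical input schemas (UTF-8, header row required):

- ``facilities.csv``: facility_id, state, locality, headcount_physician,
  headcount_nurse, headcount_hp
- ``population.csv``: facility_id, age_group, n
- ``times.csv``: facility_id, age_group, cadre, minutes_used, minutes_required
- ``activities.csv`` (optional): activity_id, age_group, cadre, minutes_used,
  minutes_required
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from hrgap.domain import (
    LOCALITIES,
    SERVICE_CADRES,
    ActivityAssignment,
    Cadre,
    FacilityProfile,
    TimeEstimate,
    ValidationError,
)
from hrgap.synth import SyntheticStudy

FACILITY_COLUMNS = [
    "facility_id",
    "state",
    "locality",
    "headcount_physician",
    "headcount_nurse",
    "headcount_hp",
]
POPULATION_COLUMNS = ["facility_id", "age_group", "n"]
TIMES_COLUMNS = ["facility_id", "age_group", "cadre", "minutes_used", "minutes_required"]
ACTIVITY_COLUMNS = ["activity_id", "age_group", "cadre", "minutes_used", "minutes_required"]

_CADRE_HEADER = {
    Cadre.PHYSICIAN: "headcount_physician",
    Cadre.NURSE: "headcount_nurse",
    Cadre.HEALTH_PROMOTER: "headcount_hp",
}


@dataclass(frozen=True)
class Violation:
    file: str
    row: int | None
    column: str | None
    message: str

    def __str__(self) -> str:
        loc = self.file
        if self.row is not None:
            loc += f" row {self.row}"
        if self.column is not None:
            loc += f" column {self.column}"
        return f"{loc}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)
    n_activities: int | None = None

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, file: str, row: int | None, column: str | None, message: str) -> None:
        self.violations.append(Violation(file, row, column, message))


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def study_frames(study: SyntheticStudy) -> dict[str, pd.DataFrame]:
    """Render a study as the four canonical tables."""
    facilities = pd.DataFrame(
        [
            {
                "facility_id": f.facility_id,
                "state": f.state,
                "locality": f.locality,
                "headcount_physician": f.headcount.get(Cadre.PHYSICIAN, 0),
                "headcount_nurse": f.headcount.get(Cadre.NURSE, 0),
                "headcount_hp": f.headcount.get(Cadre.HEALTH_PROMOTER, 0),
            }
            for f in study.facilities
        ],
        columns=FACILITY_COLUMNS,
    )
    population = pd.DataFrame(
        [
            {"facility_id": f.facility_id, "age_group": g, "n": n}
            for f in study.facilities
            for g, n in f.population.items()
        ],
        columns=POPULATION_COLUMNS,
    )
    times = pd.DataFrame(
        [
            {
                "facility_id": t.facility_id,
                "age_group": t.age_group,
                "cadre": t.cadre.value,
                "minutes_used": t.tu,
                "minutes_required": t.tr,
            }
            for t in study.times
        ],
        columns=TIMES_COLUMNS,
    )
    activities = pd.DataFrame(
        [
            {
                "activity_id": a.activity_id,
                "age_group": a.age_group,
                "cadre": a.cadre.value,
                "minutes_used": a.annual_minutes_used,
                "minutes_required": a.annual_minutes_required,
            }
            for a in study.activities
        ],
        columns=ACTIVITY_COLUMNS,
    )
    return {
        "facilities": facilities,
        "population": population,
        "times": times,
        "activities": activities,
    }


def write_study(study: SyntheticStudy, out_dir: str | Path) -> list[Path]:
    """Write the four CSVs plus ``manifest.yaml``; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    frames = study_frames(study)
    for name, frame in frames.items():
        if name == "activities" and frame.empty:
            continue
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(path)
    manifest = out / "manifest.yaml"
    with manifest.open("w") as fh:
        yaml.safe_dump(study.manifest, fh, sort_keys=True)
    written.append(manifest)
    return written


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"missing input file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return frame


def read_study(input_dir: str | Path) -> SyntheticStudy:
    """Load a study directory back into domain objects (lossless round trip)."""
    input_dir = Path(input_dir)
    fac = _read_csv(input_dir / "facilities.csv", FACILITY_COLUMNS)
    pop = _read_csv(input_dir / "population.csv", POPULATION_COLUMNS)
    tim = _read_csv(input_dir / "times.csv", TIMES_COLUMNS)

    pop_by_fac: dict[str, dict[str, int]] = {}
    for rec in pop.itertuples(index=False):
        pop_by_fac.setdefault(str(rec.facility_id), {})[str(rec.age_group)] = int(rec.n)

    facilities = []
    for rec in fac.itertuples(index=False):
        fid = str(rec.facility_id)
        facilities.append(
            FacilityProfile(
                facility_id=fid,
                state=str(rec.state),
                locality=str(rec.locality),
                headcount={
                    Cadre.PHYSICIAN: int(rec.headcount_physician),
                    Cadre.NURSE: int(rec.headcount_nurse),
                    Cadre.HEALTH_PROMOTER: int(rec.headcount_hp),
                },
                population=pop_by_fac.get(fid, {}),
            )
        )

    times = [
        TimeEstimate(
            facility_id=str(rec.facility_id),
            age_group=str(rec.age_group),
            cadre=Cadre(rec.cadre),
            tu=float(rec.minutes_used),
            tr=float(rec.minutes_required),
        )
        for rec in tim.itertuples(index=False)
    ]

    activities = []
    act_path = input_dir / "activities.csv"
    if act_path.exists():
        act = _read_csv(act_path, ACTIVITY_COLUMNS)
        activities = [
            ActivityAssignment(
                activity_id=str(rec.activity_id),
                age_group=str(rec.age_group),
                cadre=Cadre(rec.cadre),
                annual_minutes_used=float(rec.minutes_used),
                annual_minutes_required=float(rec.minutes_required),
            )
            for rec in act.itertuples(index=False)
        ]

    manifest = {}
    manifest_path = input_dir / "manifest.yaml"
    if manifest_path.exists():
        with manifest_path.open() as fh:
            manifest = yaml.safe_load(fh) or {}

    return SyntheticStudy(
        facilities=facilities,
        times=times,
        activities=activities,
        age_groups=[],
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_inputs(input_dir: str | Path) -> ValidationReport:
    """Schema and referential-integrity checks; one violation per offending cell."""
    input_dir = Path(input_dir)
    report = ValidationReport()
    if not input_dir.is_dir():
        report.add(str(input_dir), None, None, "input directory does not exist")
        return report

    frames: dict[str, pd.DataFrame] = {}
    specs = {
        "facilities.csv": FACILITY_COLUMNS,
        "population.csv": POPULATION_COLUMNS,
        "times.csv": TIMES_COLUMNS,
    }
    for name, columns in specs.items():
        path = input_dir / name
        if not path.exists():
            report.add(name, None, None, "missing required file")
            continue
        frame = pd.read_csv(path)
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            report.add(name, None, None, f"missing columns {missing}")
            continue
        frames[name] = frame

    fac = frames.get("facilities.csv")
    known_facilities: set[str] = set()
    if fac is not None:
        for i, rec in enumerate(fac.itertuples(index=False), start=2):
            fid = str(rec.facility_id)
            if fid in known_facilities:
                report.add("facilities.csv", i, "facility_id", f"duplicate id {fid!r}")
            known_facilities.add(fid)
            if str(rec.locality) not in LOCALITIES:
                report.add(
                    "facilities.csv",
                    i,
                    "locality",
                    f"must be one of {LOCALITIES}, got {rec.locality!r}",
                )
            for col in ("headcount_physician", "headcount_nurse", "headcount_hp"):
                value = getattr(rec, col)
                if pd.isna(value) or value < 0 or int(value) != value:
                    report.add(
                        "facilities.csv", i, col, f"must be a non-negative integer, got {value!r}"
                    )

    pop = frames.get("population.csv")
    pop_groups: dict[str, set[str]] = {}
    if pop is not None:
        for i, rec in enumerate(pop.itertuples(index=False), start=2):
            fid = str(rec.facility_id)
            if known_facilities and fid not in known_facilities:
                report.add("population.csv", i, "facility_id", f"unknown facility {fid!r}")
            if pd.isna(rec.n) or rec.n < 0 or int(rec.n) != rec.n:
                report.add(
                    "population.csv", i, "n", f"must be a non-negative integer, got {rec.n!r}"
                )
            pop_groups.setdefault(fid, set()).add(str(rec.age_group))

    tim = frames.get("times.csv")
    valid_cadres = {c.value for c in SERVICE_CADRES} | {Cadre.OTHER.value}
    if tim is not None:
        for i, rec in enumerate(tim.itertuples(index=False), start=2):
            fid = str(rec.facility_id)
            if known_facilities and fid not in known_facilities:
                report.add("times.csv", i, "facility_id", f"unknown facility {fid!r}")
            if str(rec.cadre) not in valid_cadres:
                report.add("times.csv", i, "cadre", f"unknown cadre {rec.cadre!r}")
            for col in ("minutes_used", "minutes_required"):
                value = getattr(rec, col)
                if pd.isna(value) or value < 0:
                    report.add("times.csv", i, col, f"must be >= 0, got {value!r}")
            if fid in pop_groups and str(rec.age_group) not in pop_groups[fid]:
                report.add(
                    "times.csv",
                    i,
                    "age_group",
                    f"no population entry for age group {rec.age_group!r} at {fid!r}",
                )

    act_path = input_dir / "activities.csv"
    if act_path.exists():
        act = pd.read_csv(act_path)
        missing = [c for c in ACTIVITY_COLUMNS if c not in act.columns]
        if missing:
            report.add("activities.csv", None, None, f"missing columns {missing}")
        else:
            seen: set[tuple[str, str]] = set()
            for i, rec in enumerate(act.itertuples(index=False), start=2):
                key = (str(rec.age_group), str(rec.activity_id))
                if key in seen:
                    report.add(
                        "activities.csv", i, "activity_id", f"duplicate id {key[1]!r} in group {key[0]!r}"
                    )
                seen.add(key)
                if str(rec.cadre) not in valid_cadres:
                    report.add("activities.csv", i, "cadre", f"unknown cadre {rec.cadre!r}")
                for col in ("minutes_used", "minutes_required"):
                    value = getattr(rec, col)
                    if pd.isna(value) or value < 0:
                        report.add("activities.csv", i, col, f"must be >= 0, got {value!r}")
            report.n_activities = len(act)

    return report
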