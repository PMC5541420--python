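"""Analysis stages: supply accounting, paired tests, summaries, sensitivity.

Each stage consumes domain objects (or the tidy frame of a previous stage)
and returns a tidy :class:`pandas.DataFrame`; :func:`run_pipeline` chains
them and collects the results in a :class:`ReportBundle`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hrgap.domain import (
    SERVICE_CADRES,
    Cadre,
    EstimationConfig,
    FacilityProfile,
    TimeEstimate,
    ValidationError,
    aggregate_median,
    available_supply_hours,
    hours_to_fte,
    ideal_supply_hours,
    round_half_up,
    summarize_times,
    supply_gap,
)
from hrgap.gamma import fit_gamma
from hrgap.stats import friedman_test, proportion_ci, wilcoxon_signed_rank
from hrgap.synth import SyntheticStudy

logger = logging.getLogger("hrgap")


@dataclass
class ReportBundle:
    """All rendered analysis tables for one study."""

    supply: pd.DataFrame
    stratum_summary: pd.DataFrame
    fte: pd.DataFrame
    fte_medians: pd.DataFrame
    time_summary: pd.DataFrame
    composition: pd.DataFrame
    sensitivity: pd.DataFrame

    def frames(self) -> dict[str, pd.DataFrame]:
        return {
            "supply": self.supply,
            "stratum_summary": self.stratum_summary,
            "fte": self.fte,
            "fte_medians": self.fte_medians,
            "time_summary": self.time_summary,
            "composition": self.composition,
            "sensitivity": self.sensitivity,
        }

    def write(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in self.frames().items():
            path = out / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        rendered = out / "report.txt"
        rendered.write_text(self.render())
        written.append(rendered)
        return written

    def render(self) -> str:
        """Plain-text report; every cell recomputed from the tidy frames."""
        sections = []
        titles = {
            "time_summary": "Median per-person annual minutes by age group",
            "stratum_summary": "Available vs ideal annual hours by stratum and cadre",
            "fte_medians": "Supply as worker counts (FTE medians)",
            "composition": "Workforce and population composition",
            "sensitivity": "Gamma-shape sensitivity of median summaries",
        }
        for name, title in titles.items():
            frame = self.frames()[name].copy()
            for col in frame.columns:
                if pd.api.types.is_float_dtype(frame[col]):
                    frame[col] = frame[col].map(
                        lambda v: round_half_up(v, 1) if pd.notna(v) else v
                    )
            sections.append(f"== {title} ==\n{frame.to_string(index=False)}\n")
        return "\n".join(sections)


# ---------------------------------------------------------------------------
# Stage 1-2: supply accounting
# ---------------------------------------------------------------------------


def compute_supply(
    facilities: Sequence[FacilityProfile],
    times: Iterable[TimeEstimate],
    config: EstimationConfig | None = None,
) -> pd.DataFrame:
    """Per facility x cadre: available and ideal annual hours, FTE, gaps."""
    config = config or EstimationConfig()
    times_by_key: dict[tuple[str, Cadre], list[TimeEstimate]] = {}
    for t in times:
        times_by_key.setdefault((t.facility_id, t.cadre), []).append(t)

    rows = []
    for f in facilities:
        for cadre in SERVICE_CADRES:
            headcount = int(f.headcount.get(cadre, 0))
            as_hours = available_supply_hours(headcount, config)
            cadre_times = times_by_key.get((f.facility_id, cadre), [])
            ideal = ideal_supply_hours(cadre_times, f.population)
            rows.append(
                {
                    "facility_id": f.facility_id,
                    "locality": f.locality,
                    "cadre": cadre.value,
                    "headcount": headcount,
                    "as_hours": as_hours,
                    "is_tu_hours": ideal.tu,
                    "is_tr_hours": ideal.tr,
                    "gap_tu_hours": supply_gap(as_hours, ideal.tu),
                    "gap_tr_hours": supply_gap(as_hours, ideal.tr),
                    "available_fte": hours_to_fte(as_hours, config),
                    "ideal_fte_tu": hours_to_fte(ideal.tu, config),
                    "ideal_fte_tr": hours_to_fte(ideal.tr, config),
                }
            )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["gap_fte_tu"] = frame["available_fte"] - frame["ideal_fte_tu"]
        frame["gap_fte_tr"] = frame["available_fte"] - frame["ideal_fte_tr"]
    logger.info("compute_supply: %d facility x cadre rows", len(frame))
    return frame


def _strata(supply: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    out = [
        (loc, supply[supply["locality"] == loc])
        for loc in ("urban", "rural")
        if (supply["locality"] == loc).any()
    ]
    out.append(("total", supply))
    return out


def stratum_supply_summary(supply: pd.DataFrame) -> pd.DataFrame:
    """Hour totals, medians, median gaps, and paired tests per stratum x cadre."""
    rows = []
    for stratum, sub_all in _strata(supply):
        for cadre in SERVICE_CADRES:
            sub = sub_all[sub_all["cadre"] == cadre.value]
            if sub.empty:
                continue
            med_as = aggregate_median(sub["as_hours"].tolist())
            med_tu = aggregate_median(sub["is_tu_hours"].tolist())
            med_tr = aggregate_median(sub["is_tr_hours"].tolist())
            w_tu = wilcoxon_signed_rank(list(zip(sub["as_hours"], sub["is_tu_hours"])))
            w_tr = wilcoxon_signed_rank(list(zip(sub["as_hours"], sub["is_tr_hours"])))
            fried = friedman_test(
                [sub["as_hours"].tolist(), sub["is_tu_hours"].tolist(), sub["is_tr_hours"].tolist()]
            )
            rows.append(
                {
                    "stratum": stratum,
                    "cadre": cadre.value,
                    "n_facilities": len(sub),
                    "total_as_hours": sub["as_hours"].sum(),
                    "total_is_tu_hours": sub["is_tu_hours"].sum(),
                    "total_is_tr_hours": sub["is_tr_hours"].sum(),
                    "median_as_hours": med_as,
                    "median_is_tu_hours": med_tu,
                    "median_is_tr_hours": med_tr,
                    "gap_tu_hours": supply_gap(med_as, med_tu),
                    "gap_tr_hours": supply_gap(med_as, med_tr),
                    "wilcoxon_tu_p": w_tu.p_value,
                    "wilcoxon_tr_p": w_tr.p_value,
                    "wilcoxon_skipped": w_tu.skipped and w_tr.skipped,
                    "friedman_stat": fried.statistic,
                    "friedman_p": fried.p_value,
                }
            )
    return pd.DataFrame(rows)


def fte_table(supply: pd.DataFrame) -> pd.DataFrame:
    """Per-facility supply expressed as worker counts."""
    cols = [
        "facility_id",
        "locality",
        "cadre",
        "available_fte",
        "ideal_fte_tu",
        "ideal_fte_tr",
        "gap_fte_tu",
        "gap_fte_tr",
    ]
    return supply[cols].copy()


def fte_median_table(supply: pd.DataFrame) -> pd.DataFrame:
    """Stratum and general medians of the per-facility FTE columns."""
    rows = []
    for stratum, sub_all in _strata(supply):
        for cadre in SERVICE_CADRES:
            sub = sub_all[sub_all["cadre"] == cadre.value]
            if sub.empty:
                continue
            med_av = aggregate_median(sub["available_fte"].tolist())
            med_tu = aggregate_median(sub["ideal_fte_tu"].tolist())
            med_tr = aggregate_median(sub["ideal_fte_tr"].tolist())
            rows.append(
                {
                    "stratum": stratum if stratum != "total" else "general",
                    "cadre": cadre.value,
                    "available_fte": med_av,
                    "ideal_fte_tu": med_tu,
                    "ideal_fte_tr": med_tr,
                    "gap_fte_tu": supply_gap(med_av, med_tu),
                    "gap_fte_tr": supply_gap(med_av, med_tr),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage 3: descriptive summaries
# ---------------------------------------------------------------------------


def time_summary_table(times: Sequence[TimeEstimate]) -> pd.DataFrame:
    """Per-age-group and all-groups median minutes by cadre, with differences."""
    groups = sorted({t.age_group for t in times})
    summaries = [
        summarize_times([t for t in times if t.age_group == g], stratum=g) for g in groups
    ]
    summaries.append(summarize_times(times, stratum="all_groups"))
    return pd.DataFrame(
        [
            {
                "stratum": s.stratum,
                "used_total": s.used_total,
                "used_physician": s.used_physician,
                "used_nurse": s.used_nurse,
                "used_hp": s.used_hp,
                "required_total": s.required_total,
                "required_physician": s.required_physician,
                "required_nurse": s.required_nurse,
                "required_hp": s.required_hp,
                "diff_total": s.diff_total,
                "diff_physician": s.diff_physician,
                "diff_nurse": s.diff_nurse,
                "diff_hp": s.diff_hp,
                "used_total_of_medians": s.used_total_of_medians,
                "required_total_of_medians": s.required_total_of_medians,
            }
            for s in summaries
        ]
    )


def composition_summary(facilities: Sequence[FacilityProfile]) -> pd.DataFrame:
    """Cadre shares of the service-delivery workforce and the urban population share."""
    totals = {c: 0 for c in SERVICE_CADRES}
    urban_pop = 0
    total_pop = 0
    for f in facilities:
        for c in SERVICE_CADRES:
            totals[c] += int(f.headcount.get(c, 0))
        total_pop += f.total_population
        if f.locality == "urban":
            urban_pop += f.total_population
    staff_total = sum(totals.values())
    rows = []
    for c in SERVICE_CADRES:
        if staff_total > 0:
            ci = proportion_ci(totals[c], staff_total)
            rows.append(
                {
                    "quantity": f"share_{c.value}",
                    "count": totals[c],
                    "total": staff_total,
                    "percent": ci.point,
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                }
            )
    if total_pop > 0:
        ci = proportion_ci(urban_pop, total_pop)
        rows.append(
            {
                "quantity": "share_population_urban",
                "count": urban_pop,
                "total": total_pop,
                "percent": ci.point,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage 4: gamma sensitivity
# ---------------------------------------------------------------------------


def sensitivity_table(
    times: Sequence[TimeEstimate],
    facilities: Sequence[FacilityProfile] | None = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Gamma fits of tu and tr at several grouping levels.

    Levels: pooled, per cadre, per age group, and per locality when facility
    metadata is supplied.  Groupings with too few usable samples are reported
    as skipped rather than dropped silently.
    """
    locality_of = {f.facility_id: f.locality for f in (facilities or [])}

    def samples(subset: Sequence[TimeEstimate], channel: str) -> list[float]:
        values = [getattr(t, channel) for t in subset]
        return [v for v in values if v > 0]

    groupings: list[tuple[str, str, list[TimeEstimate]]] = [("pooled", "all", list(times))]
    for cadre in SERVICE_CADRES:
        groupings.append(
            ("cadre", cadre.value, [t for t in times if t.cadre == cadre])
        )
    for group in sorted({t.age_group for t in times}):
        groupings.append(
            ("age_group", group, [t for t in times if t.age_group == group])
        )
    if facilities:
        for loc in ("urban", "rural"):
            groupings.append(
                ("locality", loc, [t for t in times if locality_of.get(t.facility_id) == loc])
            )

    rows = []
    for level, label, subset in groupings:
        for channel in ("tu", "tr"):
            values = samples(subset, channel)
            row = {
                "level": level,
                "stratum": label,
                "variable": channel,
                "n": len(values),
            }
            try:
                fit = fit_gamma(values, variable=channel)
                row.update(
                    {
                        "alpha": fit.alpha,
                        "beta": fit.beta,
                        "sensitivity": fit.sensitivity,
                        "skew_ok": fit.skew_ok,
                        "skipped": False,
                    }
                )
            except ValidationError as exc:
                row.update(
                    {
                        "alpha": np.nan,
                        "beta": np.nan,
                        "sensitivity": np.nan,
                        "skew_ok": pd.NA,
                        "skipped": True,
                        "skip_reason": str(exc),
                    }
                )
            rows.append(row)
    frame = pd.DataFrame(rows)
    fitted = frame[~frame["skipped"]]
    logger.info(
        "sensitivity: %d/%d groupings fitted, min alpha %.3f",
        len(fitted),
        len(frame),
        fitted["alpha"].min() if len(fitted) else float("nan"),
    )
    return frame


def dataset_median_safe(sensitivity: pd.DataFrame) -> bool:
    """Whole-dataset verdict: every fitted grouping is median-safe."""
    fitted = sensitivity[~sensitivity["skipped"]]
    return bool(fitted["skew_ok"].all()) if len(fitted) else True


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(
    study: SyntheticStudy,
    output_dir: str | Path | None = None,
    config: EstimationConfig | None = None,
) -> ReportBundle:
    """Run all stages on a loaded study; optionally write the report files."""
    config = config or EstimationConfig()
    if not study.facilities:
        raise ValidationError("study has no facilities")
    supply = compute_supply(study.facilities, study.times, config)
    bundle = ReportBundle(
        supply=supply,
        stratum_summary=stratum_supply_summary(supply),
        fte=fte_table(supply),
        fte_medians=fte_median_table(supply),
        time_summary=time_summary_table(study.times),
        composition=composition_summary(study.facilities),
        sensitivity=sensitivity_table(study.times, study.facilities),
    )
    if output_dir is not None:
        written = bundle.write(output_dir)
        logger.info("wrote %d report files to %s", len(written), output_dir)
    return bundle
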