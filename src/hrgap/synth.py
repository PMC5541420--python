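"""Seeded synthetic-study generator.

Produces complete facility datasets with the statistical structure the
analysis assumes: 12 urban + 8 rural facilities by default, 10 age/service
groups whose activity counts sum to 99, right-skewed (gamma) per-person
service minutes with time-required stochastically exceeding time-used, an
~87/13 urban/rural split of the attended population, and cadre headcounts
whose urban health-promoter counts are mostly zero.

A single integer seed governs all draws; each facility consumes its own
sub-stream so adding facilities does not perturb existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.stats import gamma as gamma_dist

from hrgap import calibration as calib
from hrgap.domain import (
    ActivityAssignment,
    AgeGroup,
    Cadre,
    FacilityProfile,
    TimeEstimate,
    ValidationError,
)

SERVICE_CADRES = (Cadre.PHYSICIAN, Cadre.NURSE, Cadre.HEALTH_PROMOTER)


class HeadcountModel(BaseModel):
    """Gamma-Poisson headcount draw with optional zero inflation."""

    mean: float = Field(gt=0)
    dispersion: float = Field(default=3.0, gt=0)
    p_present: float = Field(default=1.0, gt=0, le=1.0)

    def draw(self, rng: np.random.Generator) -> int:
        if rng.random() >= self.p_present:
            return 0
        lam = rng.gamma(self.dispersion, self.mean / self.dispersion)
        return int(rng.poisson(lam))


def _default_group_params() -> dict[str, dict]:
    params = {}
    for g in calib.CANONICAL_GROUPS:
        used_total = g.used[0]
        req_total = g.required[0]
        shares = np.array(g.used[1:4], dtype=float)
        if shares.sum() <= 0:
            shares = np.ones(3)
        shares = shares / shares.sum()
        params[g.group.id] = {
            "label": g.group.label,
            "n_activities": g.group.n_activities,
            "median_minutes_used": used_total,
            "inflation": req_total / used_total,
            "cadre_shares": tuple(float(s) for s in shares),
            "population_share": g.population / calib.TOTAL_POPULATION,
        }
    return params


def _default_headcounts() -> dict[str, dict[str, HeadcountModel]]:
    # Calibrated to the study's per-facility staffing columns: urban physician
    # mean 118/12, rural 25/8; nurse totals 184/32; health promoters present in
    # 3 of 12 urban and 1 of 8 rural facilities.
    return {
        "urban": {
            "physician": HeadcountModel(mean=118 / 12, dispersion=3.0),
            "nurse": HeadcountModel(mean=184 / 12, dispersion=3.0),
            "health_promoter": HeadcountModel(mean=23 / 3, dispersion=2.0, p_present=0.25),
        },
        "rural": {
            "physician": HeadcountModel(mean=25 / 8, dispersion=3.0),
            "nurse": HeadcountModel(mean=32 / 8, dispersion=3.0),
            "health_promoter": HeadcountModel(mean=1.0, dispersion=2.0, p_present=0.125),
        },
    }


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic generator; defaults reproduce the study's shape."""

    n_urban: int = Field(default=12, ge=0)
    n_rural: int = Field(default=8, ge=0)
    total_population: int = Field(default=calib.TOTAL_POPULATION, gt=0)
    urban_share: float = Field(default=0.87, gt=0.0, lt=1.0)
    #: gamma shape of per-person service minutes (above the 1.33 skew threshold)
    time_shape: float = Field(default=2.5, gt=0)
    #: gamma shape of the mean-1 multiplicative noise on time-required
    #: (None disables the noise: tr = tu x inflation exactly)
    noise_shape: float | None = Field(default=50.0, gt=0)
    #: symmetric concentration of the population split across facilities
    population_concentration: float = Field(default=5.0, gt=0)
    group_params: dict[str, dict] = Field(default_factory=_default_group_params)
    headcounts: dict[str, dict[str, HeadcountModel]] = Field(
        default_factory=_default_headcounts
    )

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n_urban + self.n_rural < 2:
            raise ValueError("need at least 2 facilities")
        for gid, p in self.group_params.items():
            if p["median_minutes_used"] <= 0:
                raise ValueError(f"group {gid}: median minutes must be positive")
            if p["inflation"] <= 0:
                raise ValueError(f"group {gid}: inflation factor must be positive")
        return self


@dataclass
class SyntheticStudy:
    """A complete generated dataset in the canonical table schemas."""

    facilities: list[FacilityProfile]
    times: list[TimeEstimate]
    activities: list[ActivityAssignment]
    age_groups: list[AgeGroup]
    manifest: dict = field(default_factory=dict)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (exact sum)."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValidationError("allocation weights must have positive sum")
    raw = total * weights / weights.sum()
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


_LOCALITY_CODE = {"urban": 0, "rural": 1}


def _facility_rng(seed: int, tag: int, locality: str, index: int) -> np.random.Generator:
    # keyed by locality + within-locality index so adding facilities of one
    # locality leaves every existing facility's draws untouched
    return np.random.default_rng(
        np.random.SeedSequence([seed, tag, _LOCALITY_CODE[locality], index])
    )


def _iter_facilities(config: GeneratorConfig) -> Iterator[tuple[int, str, str]]:
    for i in range(config.n_urban):
        yield i, f"U{i + 1:02d}", "urban"
    for i in range(config.n_rural):
        yield i, f"R{i + 1:02d}", "rural"


def generate_study(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Draw a full synthetic study, reproducible from ``seed``."""
    config = config or GeneratorConfig()
    group_ids = list(config.group_params)
    unit_median = float(gamma_dist.ppf(0.5, config.time_shape))

    # Population split: locality totals, then per-facility gamma weights
    # (normalized -> symmetric Dirichlet) drawn from per-facility sub-streams.
    urban_total = round(config.total_population * config.urban_share)
    rural_total = config.total_population - urban_total
    weights = {}
    for idx, fid, locality in _iter_facilities(config):
        rng = _facility_rng(seed, 1, locality, idx)
        weights[fid] = rng.gamma(config.population_concentration, 1.0)
    urban_ids = [fid for _, fid, loc in _iter_facilities(config) if loc == "urban"]
    rural_ids = [fid for _, fid, loc in _iter_facilities(config) if loc == "rural"]
    totals: dict[str, int] = {}
    if urban_ids:
        alloc = _largest_remainder(
            urban_total, np.array([weights[f] for f in urban_ids])
        )
        totals.update(dict(zip(urban_ids, alloc.tolist())))
    if rural_ids:
        alloc = _largest_remainder(
            rural_total, np.array([weights[f] for f in rural_ids])
        )
        totals.update(dict(zip(rural_ids, alloc.tolist())))

    group_shares = np.array(
        [config.group_params[g]["population_share"] for g in group_ids]
    )

    facilities: list[FacilityProfile] = []
    times: list[TimeEstimate] = []
    for idx, fid, locality in _iter_facilities(config):
        rng = _facility_rng(seed, 2, locality, idx)
        pop_alloc = _largest_remainder(totals[fid], group_shares)
        population = dict(zip(group_ids, (int(v) for v in pop_alloc)))
        headcount = {
            cadre: config.headcounts[locality][cadre.value].draw(rng)
            for cadre in SERVICE_CADRES
        }
        facilities.append(
            FacilityProfile(
                facility_id=fid,
                state=f"state_{idx % 10 + 1:02d}",
                locality=locality,
                headcount=headcount,
                population=population,
            )
        )
        for gid in group_ids:
            p = config.group_params[gid]
            scale = p["median_minutes_used"] / unit_median
            total_tu = float(rng.gamma(config.time_shape, scale))
            if config.noise_shape is None:
                noise = 1.0
            else:
                noise = float(rng.gamma(config.noise_shape, 1.0 / config.noise_shape))
            total_tr = total_tu * p["inflation"] * noise
            for cadre, share in zip(SERVICE_CADRES, p["cadre_shares"]):
                if share <= 0:
                    continue
                times.append(
                    TimeEstimate(
                        facility_id=fid,
                        age_group=gid,
                        cadre=cadre,
                        tu=total_tu * share,
                        tr=total_tr * share,
                    )
                )

    age_groups = [
        AgeGroup(gid, config.group_params[gid]["label"], config.group_params[gid]["n_activities"])
        for gid in group_ids
    ]
    activities = _package_activities(config)
    manifest = {
        "seed": seed,
        "config": config.model_dump(),
        "n_facilities": len(facilities),
    }
    return SyntheticStudy(
        facilities=facilities,
        times=times,
        activities=activities,
        age_groups=age_groups,
        manifest=manifest,
    )


def _package_activities(config: GeneratorConfig) -> list[ActivityAssignment]:
    """Split each group's per-cadre minutes uniformly across its activities.

    Activities are assigned to cadres proportional to the cadre time shares,
    so per-(group, cadre) sums reproduce the group totals exactly.
    """
    activities: list[ActivityAssignment] = []
    for gid, p in config.group_params.items():
        n_act = int(p["n_activities"])
        if n_act == 0:
            continue
        shares = np.array(p["cadre_shares"], dtype=float)
        counts = _largest_remainder(n_act, np.where(shares > 0, shares, 0.0))
        used_total = p["median_minutes_used"]
        req_total = used_total * p["inflation"]
        k = 0
        for cadre, share, count in zip(SERVICE_CADRES, shares, counts):
            if count == 0:
                continue
            for _ in range(count):
                k += 1
                activities.append(
                    ActivityAssignment(
                        activity_id=f"{gid}_{k:02d}",
                        age_group=gid,
                        cadre=cadre,
                        annual_minutes_used=used_total * share / count,
                        annual_minutes_required=req_total * share / count,
                    )
                )
    return activities


def degenerate_study(kind: str, seed: int = 0) -> SyntheticStudy:
    """Fixtures with known truth: ``no_gap``, ``all_gap`` or ``zero_promoters``."""
    if kind == "no_gap":
        return _no_gap_study()
    if kind == "all_gap":
        return _all_gap_study()
    if kind == "zero_promoters":
        return _zero_promoters_study(seed)
    raise ValidationError(f"unknown degenerate study kind {kind!r}")


_DEGENERATE_GROUP = AgeGroup("all", "All age groups", 99)


def _no_gap_study() -> SyntheticStudy:
    """Ideal supply exactly equals available supply at every facility."""
    facilities = []
    times = []
    headcounts = [3, 5, 2, 4]
    populations = [6000, 12000, 3000, 9000]
    for i, (h, pop) in enumerate(zip(headcounts, populations)):
        fid = f"NG{i + 1:02d}"
        locality = "urban" if i % 2 == 0 else "rural"
        facilities.append(
            FacilityProfile(
                facility_id=fid,
                state="state_01",
                locality=locality,
                headcount={c: h for c in SERVICE_CADRES},
                population={"all": pop},
            )
        )
        minutes = h * 1200.0 * 60.0 / pop  # ideal hours == h * 1200 exactly
        for cadre in SERVICE_CADRES:
            times.append(TimeEstimate(fid, "all", cadre, minutes, minutes))
    return SyntheticStudy(
        facilities=facilities,
        times=times,
        activities=[],
        age_groups=[_DEGENERATE_GROUP],
        manifest={"kind": "no_gap"},
    )


def _all_gap_study() -> SyntheticStudy:
    """Every facility is short in every cadre (large effect, n = 12)."""
    facilities = []
    times = []
    for i in range(12):
        fid = f"AG{i + 1:02d}"
        pop = 4000 + 500 * i
        facilities.append(
            FacilityProfile(
                facility_id=fid,
                state="state_01",
                locality="urban" if i < 7 else "rural",
                headcount={c: 1 for c in SERVICE_CADRES},
                population={"all": pop},
            )
        )
        for cadre in SERVICE_CADRES:
            # ~10x the minutes that one worker could deliver
            minutes = 10 * 1200.0 * 60.0 / pop
            times.append(TimeEstimate(fid, "all", cadre, minutes, minutes * 1.5))
    return SyntheticStudy(
        facilities=facilities,
        times=times,
        activities=[],
        age_groups=[_DEGENERATE_GROUP],
        manifest={"kind": "all_gap"},
    )


def _zero_promoters_study(seed: int) -> SyntheticStudy:
    """Health-promoter headcount zero everywhere with positive HP demand."""
    config = GeneratorConfig()
    config.headcounts["urban"]["health_promoter"] = HeadcountModel(
        mean=1e-9, p_present=1.0
    )
    config.headcounts["rural"]["health_promoter"] = HeadcountModel(
        mean=1e-9, p_present=1.0
    )
    study = generate_study(config, seed=seed)
    facilities = [
        FacilityProfile(
            facility_id=f.facility_id,
            state=f.state,
            locality=f.locality,
            headcount={**dict(f.headcount), Cadre.HEALTH_PROMOTER: 0},
            population=f.population,
        )
        for f in study.facilities
    ]
    study.facilities = facilities
    study.manifest["kind"] = "zero_promoters"
    return study
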