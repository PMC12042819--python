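"""Synthetic frames, populations and surveys for design calibration.

The generator emulates the structure of a national health system: provinces
containing district-level health zones (HZ), each divided into 4–41 health
areas (HA) of 5 000–10 000 people.  Within an HA, eligible households (those
with a child aged 6–23 months) sit in the cells of the 4x4 quadrant grid.

Vaccination status is generated hierarchically:

* each HZ has a mean coverage ``mu`` (Gaussian around the model mean,
  clipped);
* each HA draws its coverage from a Beta distribution with mean ``mu`` whose
  concentration is set from the requested child-level intra-cluster
  correlation via the closed form ``ICC = 1 / (1 + alpha + beta)``, i.e.
  ``alpha + beta = (1 - ICC) / ICC``;
* a "pocketing" gradient optionally tilts coverage on the logit scale
  towards the centre of the HA grid, emulating the field observation that
  households near the health centre share higher coverage;
* each child is Bernoulli given its cell coverage.  Unvaccinated children
  may be partially vaccinated (BCG + first pentavalent dose) so the
  zero-dose, pentavalent and fully-vaccinated indicators are distinct.

:func:`run_survey` executes the full three-stage design against the
synthetic rosters and emits standard child records; :func:`calibrate` runs
the design → survey → estimate loop over many replicates to measure
estimator bias, confidence-interval coverage and design effects; and
:func:`pocket_experiment` contrasts the legacy near-centre segment listing
with the quadrant procedure on a pocketed population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import binomtest

from vcsurvey.design import (
    AreaPlan,
    DesignConfig,
    SamplingPlan,
    SegmentPlan,
    ZonePlan,
    replace_absent_household,
    segment_legacy,
    segment_quadrant,
    select_primary_units,
    systematic_sample_households,
    _split_quota,
)
from vcsurvey.estimate import estimate_coverage
from vcsurvey.frame import ChildRecord, Dose, HealthArea, HealthZone, Province, SamplingFrame
from vcsurvey.indicators import DEFAULT_SCHEDULE, indicator_table

__all__ = [
    "CalibrationReport",
    "PocketEffectResult",
    "PopulationModel",
    "ScenarioResult",
    "SurveyResult",
    "TruePopulation",
    "calibrate",
    "generate_frame",
    "generate_population",
    "pocket_experiment",
    "run_survey",
    "simulated_design_effect",
]


#: Table-3-style HA-count bands: (low, high, probability).  Band means give
#: an expected HA count per HZ of about 18.
_HA_COUNT_BANDS: tuple[tuple[int, int, float], ...] = (
    (4, 10, 0.083),
    (11, 20, 0.580),
    (21, 25, 0.222),
    (26, 30, 0.085),
    (31, 41, 0.031),
)


@dataclass(frozen=True)
class PopulationModel:
    """Parameters of the synthetic frame and population generator.

    Structural defaults mirror the national system: 26 provinces, 519 HZs
    with 11–36 HZs per province, HA counts drawn from the banded
    distribution above (range 4–41, mean ~18), and HA populations uniform on
    5 000–10 000 persons.  ``eligible_fraction`` (children aged 6–23 months
    per person, default 0.05, consistent with an ~18-month birth cohort at a
    high crude birth rate) sets roster sizes; coverage parameters control
    the between-cluster correlation and spatial pocketing described in the
    module docstring.
    """

    n_provinces: int = 26
    hz_per_province: int | None = None
    total_hz: int = 519
    ha_per_hz: int | None = None
    ha_population: tuple[int, int] = (5000, 10000)
    grid: tuple[int, int] = (4, 4)
    eligible_fraction: float = 0.05
    multi_child_prob: float = 0.05
    hz_coverage_mean: float = 0.6
    hz_coverage_sd: float = 0.1
    icc: float = 0.05
    pocketing: float = 0.0
    card_possession_prob: float = 0.6
    facility_traceback_prob: float = 0.3
    partial_if_unvaccinated: float = 0.3
    absence_prob: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "eligible_fraction",
            "multi_child_prob",
            "hz_coverage_mean",
            "card_possession_prob",
            "facility_traceback_prob",
            "partial_if_unvaccinated",
            "absence_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError(
                f"icc={self.icc} unattainable: the Beta parameterisation "
                "requires 0 <= icc < 1"
            )
        if self.ha_population[0] <= 0 or self.ha_population[1] < self.ha_population[0]:
            raise ValueError(f"invalid ha_population range {self.ha_population}")
        if self.n_provinces < 1:
            raise ValueError("n_provinces must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.grid[0] * self.grid[1]

    @classmethod
    def calibration_default(cls, icc: float = 0.05, **overrides) -> "PopulationModel":
        """One typical HZ of 18 HAs: the unit of the calibration loop."""
        base = dict(
            n_provinces=1, hz_per_province=1, total_hz=1, ha_per_hz=18,
            icc=icc, pocketing=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def pocketed_default(cls, **overrides) -> "PopulationModel":
        """A strongly pocketed single-HZ population for the bias experiment."""
        base = dict(
            n_provinces=1, hz_per_province=1, total_hz=1, ha_per_hz=18,
            icc=0.05, pocketing=2.0, hz_coverage_sd=0.1,
        )
        base.update(overrides)
        return cls(**base)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Frame generation


def _draw_hz_counts(model: PopulationModel, rng: np.random.Generator) -> np.ndarray:
    if model.hz_per_province is not None:
        return np.full(model.n_provinces, model.hz_per_province, dtype=int)
    counts = rng.integers(11, 37, size=model.n_provinces)
    # nudge towards the configured national total while staying in [11, 36]
    diff = model.total_hz - int(counts.sum())
    step = 1 if diff > 0 else -1
    i = 0
    while diff != 0 and model.n_provinces > 0:
        j = i % model.n_provinces
        if 11 <= counts[j] + step <= 36:
            counts[j] += step
            diff -= step
        i += 1
        if i > 100 * model.n_provinces:
            break
    return counts


def generate_frame(
    model: PopulationModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> SamplingFrame:
    """Draw a synthetic sampling frame from the structural model.

    Per-HZ HA counts come from the banded distribution (support [4, 41],
    mean ~18) unless ``model.ha_per_hz`` fixes them; HA populations are
    uniform on the configured range.
    """
    model = model or PopulationModel()
    rng = _as_rng(rng)
    hz_counts = _draw_hz_counts(model, rng)
    lows = np.array([b[0] for b in _HA_COUNT_BANDS])
    highs = np.array([b[1] for b in _HA_COUNT_BANDS])
    probs = np.array([b[2] for b in _HA_COUNT_BANDS])
    probs = probs / probs.sum()
    provinces = []
    for p in range(model.n_provinces):
        zones = []
        for z in range(hz_counts[p]):
            if model.ha_per_hz is not None:
                n_ha = model.ha_per_hz
            else:
                band = rng.choice(len(probs), p=probs)
                n_ha = int(rng.integers(lows[band], highs[band] + 1))
            areas = [
                HealthArea(
                    name=f"P{p + 1:02d}Z{z + 1:02d}A{a + 1:02d}",
                    population=int(rng.integers(model.ha_population[0], model.ha_population[1] + 1)),
                )
                for a in range(n_ha)
            ]
            zones.append(HealthZone(name=f"P{p + 1:02d}Z{z + 1:02d}", areas=areas))
        provinces.append(Province(name=f"P{p + 1:02d}", zones=zones))
    return SamplingFrame(provinces=provinces)


# ---------------------------------------------------------------------------
# Population generation


def _cell_gradient(grid: tuple[int, int]) -> np.ndarray:
    """Centred near-centre gradient per cell (row-major), mean zero.

    Cells closer to the grid centre get larger values, so a positive
    pocketing coefficient raises coverage near the (central) health centre.
    """
    gr, gc = grid
    rows, cols = np.divmod(np.arange(gr * gc), gc)
    cy = (rows + 0.5) / gr - 0.5
    cx = (cols + 0.5) / gc - 0.5
    d = np.hypot(cy, cx)
    g = -d / d.max()
    return g - g.mean()


def _cell_centre_order(grid: tuple[int, int]) -> np.ndarray:
    """Cell ids (1-based) sorted by distance from the grid centre."""
    gr, gc = grid
    rows, cols = np.divmod(np.arange(gr * gc), gc)
    d = np.hypot((rows + 0.5) / gr - 0.5, (cols + 0.5) / gc - 0.5)
    return np.argsort(d, kind="stable") + 1


@dataclass
class TruePopulation:
    """Ground-truth synthetic population: full household/child rosters.

    ``children`` has one row per eligible child with columns ``province,
    health_zone, health_area, cell, household, child, age_months,
    vaccinated, partial, card``; ``ha_info`` records the latent HA coverage
    and realised child counts; ``hz_mean`` maps (province, HZ) to the latent
    HZ mean coverage ``mu``.
    """

    model: PopulationModel
    frame: SamplingFrame
    children: pd.DataFrame
    ha_info: pd.DataFrame
    hz_mean: dict[tuple[str, str], float]
    cell_coverage: dict[tuple[str, str, str], np.ndarray]
    _hh_index: dict | None = field(default=None, repr=False)

    def realized_hz_coverage(self, province: str, health_zone: str) -> float:
        """Realised vaccinated proportion among all eligible children of a HZ."""
        mask = (self.children["province"] == province) & (
            self.children["health_zone"] == health_zone
        )
        sub = self.children.loc[mask, "vaccinated"]
        if sub.empty:
            raise ValueError(f"no children in {province}/{health_zone}")
        return float(sub.mean())

    def household_index(self) -> dict:
        """(province, hz, ha) -> {cell -> array of household ids}."""
        if self._hh_index is None:
            hh = self.children.drop_duplicates(
                subset=["province", "health_zone", "health_area", "household"]
            )
            households = hh["household"].to_numpy()
            grouped = hh.groupby(
                ["province", "health_zone", "health_area", "cell"], sort=True
            ).indices
            index: dict = {}
            for (prov, hz, ha, cell), pos in grouped.items():
                index.setdefault((prov, hz, ha), {})[int(cell)] = households[pos]
            self._hh_index = index
        return self._hh_index


def generate_population(
    frame: SamplingFrame,
    model: PopulationModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> TruePopulation:
    """Generate the full eligible-household/child roster for a frame."""
    model = model or PopulationModel()
    rng = _as_rng(rng)
    gradient = _cell_gradient(model.grid)
    n_cells = model.n_cells

    frames: list[pd.DataFrame] = []
    ha_rows = []
    hz_mean: dict[tuple[str, str], float] = {}
    cell_cov: dict[tuple[str, str, str], np.ndarray] = {}
    for prov, hz in frame.iter_zones():
        mu = float(np.clip(
            rng.normal(model.hz_coverage_mean, model.hz_coverage_sd), 0.02, 0.98
        ))
        hz_mean[(prov.name, hz.name)] = mu
        for area in hz.areas:
            pop = area.population or int(
                rng.integers(model.ha_population[0], model.ha_population[1] + 1)
            )
            n_child = int(rng.binomial(pop, model.eligible_fraction))
            if n_child == 0:
                continue
            if model.icc == 0.0:
                c_a = mu
            else:
                s = (1.0 - model.icc) / model.icc
                c_a = float(rng.beta(mu * s, (1.0 - mu) * s))
                c_a = min(max(c_a, 1e-6), 1 - 1e-6)
            c_cells = expit(logit(c_a) + model.pocketing * gradient)
            cell_cov[(prov.name, hz.name, area.name)] = c_cells

            # households: a few hold two eligible children, the rest one
            n_pairs = int(rng.binomial(n_child // 2, model.multi_child_prob))
            n_hh = n_child - n_pairs
            hh_of_child = np.concatenate(
                [np.repeat(np.arange(n_pairs), 2), np.arange(n_pairs, n_hh)]
            )
            hh_cell = rng.integers(1, n_cells + 1, size=n_hh)
            cell_of_child = hh_cell[hh_of_child]
            p_child = c_cells[cell_of_child - 1]
            vaccinated = rng.random(n_child) < p_child
            partial = (~vaccinated) & (
                rng.random(n_child) < model.partial_if_unvaccinated
            )
            card = rng.random(n_child) < model.card_possession_prob
            ages = rng.integers(6, 24, size=n_child)
            frames.append(
                pd.DataFrame(
                    {
                        "province": prov.name,
                        "health_zone": hz.name,
                        "health_area": area.name,
                        "cell": cell_of_child,
                        "household": hh_of_child,
                        "child": np.arange(n_child),
                        "age_months": ages,
                        "vaccinated": vaccinated,
                        "partial": partial,
                        "card": card,
                    }
                )
            )
            ha_rows.append(
                {
                    "province": prov.name,
                    "health_zone": hz.name,
                    "health_area": area.name,
                    "population": pop,
                    "n_children": n_child,
                    "coverage_latent": c_a,
                    "coverage_realized": float(vaccinated.mean()),
                }
            )
    if not frames:
        raise ValueError("model produced an empty population (no eligible children)")
    children = pd.concat(frames, ignore_index=True)
    return TruePopulation(
        model=model,
        frame=frame,
        children=children,
        ha_info=pd.DataFrame(ha_rows),
        hz_mean=hz_mean,
        cell_coverage=cell_cov,
    )


# ---------------------------------------------------------------------------
# Survey execution


@dataclass
class SurveyResult:
    records: list[ChildRecord]
    plan: SamplingPlan
    #: per-child indicator table (weights included), ready for estimation
    table: pd.DataFrame


def _full_schedule_doses(source: str) -> frozenset[Dose]:
    return frozenset(
        Dose(antigen, k, source)
        for antigen, n in DEFAULT_SCHEDULE.items()
        for k in range(1, n + 1)
    )


_PARTIAL_DOSES = (("BCG", 1), ("Penta", 1))


def _child_doses(vaccinated: bool, partial: bool, source: str) -> frozenset[Dose]:
    if vaccinated:
        return _full_schedule_doses(source)
    if partial:
        return frozenset(Dose(a, k, source) for a, k in _PARTIAL_DOSES)
    return frozenset()


def _apply_absences(
    selected: Sequence[int],
    roster_size: int,
    absence_prob: float,
    rng: np.random.Generator,
) -> list[int]:
    """Replace absent households (three failed visits) by the next-in-roster rule."""
    current = list(selected)
    if absence_prob <= 0:
        return current
    for idx in list(current):
        if rng.random() < absence_prob:
            current, _ = replace_absent_household(current, roster_size, idx)
    return current


def run_survey(
    population: TruePopulation,
    config: DesignConfig | None = None,
    rng: np.random.Generator | int | None = None,
    legacy_listing: str = "full",
) -> SurveyResult:
    """Execute the three-stage design against a synthetic population.

    ``legacy_listing`` only affects the legacy protocol: ``"full"`` lists all
    grid cells as segments, while ``"near_center"`` reproduces the field
    behaviour of listing only the half of the segments closest to the health
    centre (a biased frame — the quadrant protocol was introduced to remove
    it).
    """
    config = config or DesignConfig()
    if config.protocol == "quadrant2023" and config.quadrant_grid != population.model.grid:
        raise ValueError(
            f"config grid {config.quadrant_grid} != population grid {population.model.grid}"
        )
    if legacy_listing not in ("full", "near_center"):
        raise ValueError(f"unknown legacy_listing {legacy_listing!r}")
    rng = _as_rng(rng)
    hh_index = population.household_index()
    children = population.children
    child_groups = children.groupby(
        ["province", "health_zone", "health_area", "household"], sort=False
    ).indices
    child_cols = {
        name: children[name].to_numpy()
        for name in ("child", "age_months", "vaccinated", "partial", "card")
    }

    plan = SamplingPlan(config=config, seed=None)
    records: list[ChildRecord] = []
    for prov, hz in population.frame.iter_zones():
        psel = select_primary_units(hz, config, rng)
        zp = ZonePlan(
            province=prov.name,
            health_zone=hz.name,
            replacements=psel.replacements,
            quota_inflated=psel.quota_inflated,
        )
        for ha_name in psel.selected:
            cells_hh = hh_index.get((prov.name, hz.name, ha_name), {})
            ap = AreaPlan(
                province=prov.name,
                health_zone=hz.name,
                health_area=ha_name,
                quota=psel.quota_per_ha,
                pi1=psel.pi1,
            )
            if config.protocol == "quadrant2023":
                cells, pi2 = segment_quadrant(config, rng)
                quotas = _split_quota(psel.quota_per_ha, len(cells))
                for cell, k in zip(cells, quotas):
                    ids = cells_hh.get(cell, np.array([], dtype=object))
                    if ids.size == 0:
                        ap.segments.append(
                            SegmentPlan(
                                segment=f"Q{cell:02d}", roster_size=0, selected=(),
                                start=0.0, interval=0.0, pi2=pi2, pi3=1.0,
                                shortfall=True, roster=(),
                            )
                        )
                        continue
                    order = rng.permutation(ids.size)
                    roster = ids[order][: min(config.eligible_identified_per_segment, ids.size)]
                    draw = systematic_sample_households(len(roster), k, rng)
                    enrolled = _apply_absences(
                        list(draw.indices), len(roster),
                        population.model.absence_prob, rng,
                    )
                    sp = SegmentPlan(
                        segment=f"Q{cell:02d}",
                        roster_size=len(roster),
                        selected=tuple(enrolled),
                        start=draw.start,
                        interval=draw.interval,
                        pi2=pi2,
                        pi3=draw.pi3,
                        shortfall=draw.shortfall,
                        roster=tuple(str(h) for h in roster),
                    )
                    ap.segments.append(sp)
                    _enroll(
                        records, child_groups, child_cols, rng, population.model,
                        prov.name, hz.name, ha_name, ap.pi1, sp, roster,
                    )
            else:
                all_cells = [int(c) for c in _cell_centre_order(population.model.grid)]
                if legacy_listing == "near_center":
                    listed = all_cells[: max(1, len(all_cells) // 2)]
                else:
                    listed = sorted(all_cells)
                seg_names = [f"C{c:02d}" for c in listed]
                chosen, pi2 = segment_legacy(seg_names, config, rng)
                chosen_cells = [int(s[1:]) for s in chosen]
                pooled: list = []
                for cell in chosen_cells:
                    ids = cells_hh.get(cell, np.array([], dtype=object))
                    if ids.size:
                        ids = ids[rng.permutation(ids.size)]
                        pooled.extend(ids.tolist())
                if not pooled:
                    ap.segments.append(
                        SegmentPlan(
                            segment="+".join(chosen), roster_size=0, selected=(),
                            start=0.0, interval=0.0, pi2=pi2, pi3=1.0,
                            shortfall=True, roster=(),
                        )
                    )
                    zp.areas.append(ap)
                    continue
                draw = systematic_sample_households(len(pooled), psel.quota_per_ha, rng)
                enrolled = _apply_absences(
                    list(draw.indices), len(pooled), population.model.absence_prob, rng
                )
                sp = SegmentPlan(
                    segment="+".join(chosen),
                    roster_size=len(pooled),
                    selected=tuple(enrolled),
                    start=draw.start,
                    interval=draw.interval,
                    pi2=pi2,
                    pi3=draw.pi3,
                    shortfall=draw.shortfall,
                    roster=tuple(str(h) for h in pooled),
                )
                ap.segments.append(sp)
                _enroll(
                    records, child_groups, child_cols, rng, population.model,
                    prov.name, hz.name, ha_name, ap.pi1, sp, np.asarray(pooled),
                )
            zp.areas.append(ap)
        plan.zones.append(zp)
    table = indicator_table(records)
    return SurveyResult(records=records, plan=plan, table=table)


def _enroll(records, child_groups, child_cols, rng, model, prov, hz, ha, pi1, sp: SegmentPlan, roster) -> None:
    weight = 1.0 / (pi1 * sp.pi2 * sp.pi3)
    for idx in sp.selected:
        hh = roster[idx - 1]
        pos = child_groups.get((prov, hz, ha, int(hh)))
        if pos is None:
            continue
        for i in pos:
            card = bool(child_cols["card"][i])
            if card:
                source = "card"
            elif rng.random() < model.facility_traceback_prob:
                source = "facility"
            else:
                source = "recall"
            records.append(
                ChildRecord(
                    child_id=f"{ha}-H{hh}-C{child_cols['child'][i]}",
                    province=prov,
                    health_zone=hz,
                    health_area=ha,
                    segment=sp.segment,
                    household=f"{ha}-H{hh}",
                    age_months=int(child_cols["age_months"][i]),
                    doses=_child_doses(
                        bool(child_cols["vaccinated"][i]),
                        bool(child_cols["partial"][i]),
                        source,
                    ),
                    card_seen=card,
                    weight=weight,
                )
            )


# ---------------------------------------------------------------------------
# Calibration harness


@dataclass(frozen=True)
class ScenarioResult:
    icc: float
    n_replicates: int
    indicator: str
    mean_error: float  # percentage points, estimate - truth
    error_mc_se: float
    ci_coverage: float  # percent of replicates whose 95 % CI covers truth
    coverage_mc_se: float
    mean_deff: float
    mean_icc_est: float
    mean_n: float
    mean_cluster_size: float


@dataclass
class CalibrationReport:
    scenarios: list[ScenarioResult]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.scenarios])


def calibrate(
    model: PopulationModel | None = None,
    config: DesignConfig | None = None,
    n_replicates: int = 500,
    rng: np.random.Generator | int | None = None,
    icc_scenarios: Sequence[float] = (0.0, 0.05, 0.2),
    indicator: str = "fully_vaccinated",
    confidence: float = 0.95,
) -> CalibrationReport:
    """Monte-Carlo calibration of the full design → survey → estimate loop.

    For each ICC scenario, ``n_replicates`` single-HZ populations are drawn,
    surveyed under ``config`` and estimated at the HZ level.  The estimand is
    the latent HZ mean coverage ``mu`` of each replicate — the
    superpopulation target matching the with-replacement variance
    convention.  Reports mean signed error, empirical CI coverage, and DEFF/
    ICC summaries, all with Monte-Carlo standard errors.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    base_model = model or PopulationModel.calibration_default()
    config = config or DesignConfig()
    rng = _as_rng(rng)
    scenarios = []
    for icc in icc_scenarios:
        scen_model = PopulationModel(**{**vars(base_model), "icc": icc, "pocketing": 0.0})
        frame = generate_frame(scen_model, rng)
        errors = np.empty(n_replicates)
        covered = np.empty(n_replicates, dtype=bool)
        deffs = np.empty(n_replicates)
        iccs = np.empty(n_replicates)
        ns = np.empty(n_replicates)
        mbars = np.empty(n_replicates)
        for r in range(n_replicates):
            pop = generate_population(frame, scen_model, rng)
            survey = run_survey(pop, config, rng)
            est = estimate_coverage(
                survey.table, [indicator], level="hz", confidence=confidence
            ).iloc[0]
            (prov, hz), truth_mu = next(iter(pop.hz_mean.items()))
            truth = 100.0 * truth_mu
            errors[r] = est["estimate"] - truth
            covered[r] = est["ci_low"] <= truth <= est["ci_high"]
            deffs[r] = est["deff"]
            iccs[r] = est["icc"]
            ns[r] = est["n"]
            mbars[r] = est["mean_cluster_size"]
        cov = float(covered.mean())
        scenarios.append(
            ScenarioResult(
                icc=icc,
                n_replicates=n_replicates,
                indicator=indicator,
                mean_error=float(errors.mean()),
                error_mc_se=float(errors.std(ddof=1) / math.sqrt(n_replicates)),
                ci_coverage=100.0 * cov,
                coverage_mc_se=100.0 * math.sqrt(cov * (1 - cov) / n_replicates),
                mean_deff=float(np.nanmean(deffs)),
                mean_icc_est=float(np.nanmean(iccs)),
                mean_n=float(ns.mean()),
                mean_cluster_size=float(mbars.mean()),
            )
        )
    return CalibrationReport(scenarios=scenarios)


def simulated_design_effect(
    icc: float,
    n_clusters: int = 30,
    cluster_size: int = 30,
    n_replicates: int = 500,
    rng: np.random.Generator | int | None = None,
    mean_coverage: float = 0.5,
) -> tuple[float, float]:
    """Mean estimated DEFF over simulated equal-size clusters, with MC s.e.

    Cluster coverages are Beta with the requested child-level ICC; with
    equal clusters of size ``m`` the expectation is ``1 + (m - 1) * icc``.
    Used to check the DEFF/ICC machinery against the closed form.
    """
    from vcsurvey.estimate import design_effect

    rng = _as_rng(rng)
    clusters = np.repeat(np.arange(n_clusters), cluster_size)
    w = np.ones(n_clusters * cluster_size)
    deffs = []
    for _ in range(n_replicates):
        if icc == 0.0:
            p_c = np.full(n_clusters, mean_coverage)
        else:
            s = (1.0 - icc) / icc
            p_c = rng.beta(mean_coverage * s, (1.0 - mean_coverage) * s, size=n_clusters)
        y = (rng.random(n_clusters * cluster_size) < np.repeat(p_c, cluster_size)).astype(float)
        d = design_effect(y, w, clusters)
        if not math.isnan(d):
            deffs.append(d)
    deffs = np.asarray(deffs)
    return float(deffs.mean()), float(deffs.std(ddof=1) / math.sqrt(deffs.size))


# ---------------------------------------------------------------------------
# Pocket-effect experiment


@dataclass(frozen=True)
class PocketEffectResult:
    n_replicates: int
    bias_legacy: float  # pp, mean error of the near-centre legacy sampler
    bias_quadrant: float  # pp, mean error of the quadrant sampler
    mean_abs_error_legacy: float
    mean_abs_error_quadrant: float
    n_legacy_worse: int  # replicates where |legacy error| > |quadrant error|
    n_ties: int
    sign_test_p: float
    errors_legacy: tuple[float, ...] = ()
    errors_quadrant: tuple[float, ...] = ()


def pocket_experiment(
    model: PopulationModel | None = None,
    config: DesignConfig | None = None,
    n_replicates: int = 200,
    rng: np.random.Generator | int | None = None,
    indicator: str = "fully_vaccinated",
) -> PocketEffectResult:
    """Paired comparison of legacy near-centre vs quadrant sampling.

    Each replicate draws one pocketed population and surveys it twice — with
    the legacy protocol under the near-centre segment listing, and with the
    quadrant protocol.  Errors are measured against the realised population
    proportion.  A one-sided sign test asks whether the legacy absolute
    error exceeds the quadrant one more often than chance.
    """
    model = model or PopulationModel.pocketed_default()
    quad_config = config or DesignConfig()
    legacy_config = DesignConfig(
        protocol="legacy2020",
        n_psu_per_hz=quad_config.n_psu_per_hz,
        n_replacement_psu=quad_config.n_replacement_psu,
        households_per_ha=quad_config.households_per_ha,
        households_per_segment=quad_config.households_per_segment,
        eligible_identified_per_segment=quad_config.eligible_identified_per_segment,
    )
    rng = _as_rng(rng)
    frame = generate_frame(model, rng)
    err_l = np.empty(n_replicates)
    err_q = np.empty(n_replicates)
    for r in range(n_replicates):
        pop = generate_population(frame, model, rng)
        prov, hz = next(iter(pop.hz_mean))
        truth = 100.0 * pop.realized_hz_coverage(prov, hz)
        s_l = run_survey(pop, legacy_config, rng, legacy_listing="near_center")
        s_q = run_survey(pop, quad_config, rng)
        e_l = estimate_coverage(s_l.table, [indicator], level="hz").iloc[0]["estimate"]
        e_q = estimate_coverage(s_q.table, [indicator], level="hz").iloc[0]["estimate"]
        err_l[r] = e_l - truth
        err_q[r] = e_q - truth
    diff = np.abs(err_l) - np.abs(err_q)
    n_pos = int((diff > 0).sum())
    n_ties = int((diff == 0).sum())
    n_eff = n_replicates - n_ties
    p = binomtest(n_pos, n_eff, 0.5, alternative="greater").pvalue if n_eff else 1.0
    return PocketEffectResult(
        n_replicates=n_replicates,
        bias_legacy=float(err_l.mean()),
        bias_quadrant=float(err_q.mean()),
        mean_abs_error_legacy=float(np.abs(err_l).mean()),
        mean_abs_error_quadrant=float(np.abs(err_q).mean()),
        n_legacy_worse=n_pos,
        n_ties=n_ties,
        sign_test_p=float(p),
        errors_legacy=tuple(err_l.tolist()),
        errors_quadrant=tuple(err_q.tolist()),
    )
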