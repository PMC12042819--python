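"""Sample-size calculation and the three-stage cluster sampler.

The survey design stratifies by health zone (HZ) and proceeds in three
stages inside every HZ:

1. **Primary units (health areas).**  HAs are arranged in alphabetical order,
   numbered, and drawn equal-probability (duplicates redrawn, i.e. simple
   random sampling without replacement): five primary HAs plus two
   replacements reserved for insecure areas.  HZs with five or fewer HAs take
   all of them and inflate the per-cluster household quota so the HZ total is
   preserved.
2. **Segments.**  Two protocol variants.  The legacy (2020–21) variant lists
   named street/village segments and selects 30 % of them.  The quadrant
   (2022–23) variant partitions the HA into a 4x4 grid of 16 cells and draws
   6 a priori, dispersing households and avoiding "pocketing".
3. **Households.**  Eligible households (those with a child aged 6–23
   months) are sampled systematically from the segment roster with a
   fractional interval, five per segment in the quadrant variant — 30
   households per HA, 150 per five-cluster HZ.  A household absent after
   three visits is replaced by the next entry in the roster.

Every selected household carries stage-wise inclusion probabilities
``pi1 * pi2 * pi3`` and the base design weight ``1 / (pi1 * pi2 * pi3)``.

The per-province minimum sample size is the classical proportion formula
``n = deff * Z^2 * p * q / d^2`` with the anticipated coverage ``p``, its
complement ``q = 100 - p`` and the absolute margin of error ``d`` all on the
percent scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np

from vcsurvey.frame import HealthZone, SamplingFrame

__all__ = [
    "MICS_2018_PROVINCES",
    "AreaPlan",
    "DesignConfig",
    "PrimaryUnitSelection",
    "SampleSizeResult",
    "SampleSizeSpec",
    "SamplingPlan",
    "SegmentPlan",
    "SystematicSample",
    "ZonePlan",
    "draw_survey_plan",
    "min_sample_size",
    "replace_absent_household",
    "segment_legacy",
    "segment_quadrant",
    "select_primary_units",
    "systematic_sample_households",
]


# ---------------------------------------------------------------------------
# Sample size

#: Anticipated provincial coverage (MICS 2018 full-vaccination estimates, %)
#: used as the ``p`` input of the per-province sample-size calculation, with
#: the survey's standard deff = 1.5, Z = 1.96 and d = 10 percentage points.
MICS_2018_PROVINCES: dict[str, float] = {
    "Haut-Katanga": 45.5,
    "Haut-Lomami": 35.7,
    "Kasai Central": 41.3,
    "Kasai Oriental": 27.9,
    "Kasai": 13.9,
    "Kinshasa": 41.9,
    "Kongo Central": 48.0,
    "Kwango": 16.3,
    "Kwilu": 14.3,
    "Lomami": 26.9,
    "Ituri": 40.0,
    "Maniema": 6.6,
    "Mongala": 8.2,
    "Sankuru": 2.6,
    "Sud Kivu": 48.9,
    "Tanganyika": 21.2,
    "Tshopo": 20.7,
    "Lualaba": 21.1,
    "Maindombe": 11.9,
    "Bas-Uele": 23.8,
    "Haut-Uele": 17.5,
    "Nord-Kivu": 79.2,
    "Sud-Ubangi": 26.9,
    "Nord-Ubangi": 16.6,
    "Equateur": 28.5,
    "Tshuapa": 15.4,
}


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the minimum-sample-size formula (percent scale).

    Parameters
    ----------
    deff : float
        Anticipated design effect (>= 1 in practice; must be positive).
    z : float
        Standard-normal quantile for the confidence level (1.96 for 95 %).
    p : float
        Anticipated coverage in percent, 0 <= p <= 100.
    d : float
        Absolute margin of error in percentage points, > 0.
    """

    deff: float = 1.5
    z: float = 1.96
    p: float = 50.0
    d: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 100.0:
            raise ValueError(f"anticipated coverage p={self.p} outside [0, 100]")
        if self.d <= 0:
            raise ValueError(f"margin of error d={self.d} must be > 0")
        if self.deff < 1:
            raise ValueError(f"design effect deff={self.deff} must be >= 1")
        if self.z <= 0:
            raise ValueError(f"z={self.z} must be > 0")

    @property
    def q(self) -> float:
        """Complement of the anticipated coverage, 100 - p (percent)."""
        return 100.0 - self.p


@dataclass(frozen=True)
class SampleSizeResult:
    raw: float
    #: raw value rounded half-up to 1 decimal (reporting convention)
    reported: float
    #: smallest integer number of children meeting the minimum
    operational: int


def min_sample_size(spec: SampleSizeSpec) -> SampleSizeResult:
    """Minimum effective sample size ``deff * Z^2 * p * q / d^2`` (children).

    >>> min_sample_size(SampleSizeSpec(deff=1.5, z=1.96, p=45.5, d=10)).reported
    142.9
    """
    raw = spec.deff * spec.z**2 * spec.p * spec.q / spec.d**2
    reported = float(Decimal(repr(raw)).quantize(Decimal("0.1"), ROUND_HALF_UP))
    return SampleSizeResult(raw=raw, reported=reported, operational=math.ceil(raw))


# ---------------------------------------------------------------------------
# Design configuration


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the three-stage sampler.

    Defaults are the 2023 quadrant protocol: 5 primary HAs (+2 replacements)
    per HZ, 6 of 16 grid cells per HA, 15 eligible households identified per
    cell of which 5 are systematically sampled — 30 households per HA and 150
    per HZ.  ``protocol="legacy2020"`` switches stage 2 to the named-segment
    listing with 30 % of segments selected and stage 3 to a single
    HA-level systematic draw of ``households_per_ha`` from the pooled roster.
    """

    protocol: str = "quadrant2023"
    n_psu_per_hz: int = 5
    n_replacement_psu: int = 2
    legacy_segment_fraction: float = 0.30
    quadrant_grid: tuple[int, int] = (4, 4)
    quadrant_segments_drawn: int = 6
    households_per_segment: int = 5
    households_per_ha: int = 30
    #: eligible households identified per segment before the systematic draw
    #: (18 under the 2022 protocol, 15 under 2023)
    eligible_identified_per_segment: int = 15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("legacy2020", "quadrant2023"):
            raise ValueError(
                f"unknown protocol {self.protocol!r}; "
                "expected 'legacy2020' or 'quadrant2023'"
            )
        if self.protocol == "quadrant2023":
            ncells = self.quadrant_grid[0] * self.quadrant_grid[1]
            if self.quadrant_segments_drawn > ncells:
                raise ValueError(
                    f"cannot draw {self.quadrant_segments_drawn} segments from a "
                    f"{self.quadrant_grid[0]}x{self.quadrant_grid[1]} grid of {ncells} cells"
                )
            if self.households_per_segment * self.quadrant_segments_drawn != self.households_per_ha:
                raise ValueError(
                    "inconsistent quadrant quotas: households_per_segment * "
                    f"quadrant_segments_drawn = "
                    f"{self.households_per_segment * self.quadrant_segments_drawn} "
                    f"!= households_per_ha = {self.households_per_ha}"
                )
        if not 0 < self.legacy_segment_fraction <= 1:
            raise ValueError("legacy_segment_fraction must be in (0, 1]")
        if self.n_psu_per_hz < 1:
            raise ValueError("n_psu_per_hz must be >= 1")

    @classmethod
    def preset_2022(cls, **overrides) -> "DesignConfig":
        """The 2022 variant: 18 eligible households identified per segment."""
        return cls(eligible_identified_per_segment=18, **overrides)

    @property
    def n_cells(self) -> int:
        return self.quadrant_grid[0] * self.quadrant_grid[1]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Stage 1: primary units (health areas)


@dataclass(frozen=True)
class PrimaryUnitSelection:
    selected: tuple[str, ...]
    replacements: tuple[str, ...]
    #: per-HA household quota; inflated when the HZ has <= n_psu_per_hz HAs
    quota_per_ha: int
    quota_inflated: bool
    pi1: float


def select_primary_units(
    hz: HealthZone,
    config: DesignConfig,
    rng: np.random.Generator | int | None = None,
) -> PrimaryUnitSelection:
    """Stage 1: draw primary and replacement HAs equal-probability in one HZ.

    HAs are sorted alphabetically (locale-independent codepoint order) and
    numbered; draws come from the seeded generator with duplicates redrawn,
    which is probabilistically equivalent to SRS without replacement.  HZs
    with ``n_psu_per_hz`` or fewer HAs enrol every HA with no replacements and
    inflate the per-HA quota to ``ceil(n_psu_per_hz * households_per_ha / n)``
    so the HZ household total is preserved.
    """
    rng = _as_rng(rng)
    names = sorted((a.name for a in hz.areas))
    n = len(names)
    if n == 0:
        raise ValueError(f"health zone {hz.name!r} has no health areas")
    k = config.n_psu_per_hz
    if n <= k:
        quota = math.ceil(k * config.households_per_ha / n)
        return PrimaryUnitSelection(
            selected=tuple(names),
            replacements=(),
            quota_per_ha=quota,
            quota_inflated=quota != config.households_per_ha,
            pi1=1.0,
        )
    n_draw = min(n, k + config.n_replacement_psu)
    chosen: list[int] = []
    while len(chosen) < n_draw:
        # redraw-on-duplicate protocol == SRS without replacement
        i = int(rng.integers(0, n))
        if i not in chosen:
            chosen.append(i)
    return PrimaryUnitSelection(
        selected=tuple(names[i] for i in chosen[:k]),
        replacements=tuple(names[i] for i in chosen[k:]),
        quota_per_ha=config.households_per_ha,
        quota_inflated=False,
        pi1=k / n,
    )


# ---------------------------------------------------------------------------
# Stage 2: segments


def segment_legacy(
    roster: Sequence[str],
    config: DesignConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], float]:
    """Stage 2, legacy variant: select 30 % of named segments by SRS.

    The count is ``ceil(fraction * roster size)`` with a minimum of one, so
    the selection is never empty.  Returns the selected segments in roster
    order and the stage inclusion probability ``pi2``.
    """
    rng = _as_rng(rng)
    n = len(roster)
    if n == 0:
        raise ValueError("segment roster is empty")
    m = max(1, math.ceil(config.legacy_segment_fraction * n))
    idx = sorted(rng.choice(n, size=m, replace=False).tolist())
    return [roster[i] for i in idx], m / n


def segment_quadrant(
    config: DesignConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[int], float]:
    """Stage 2, quadrant variant: draw 6 of the 16 grid cells by SRS.

    Cells are identified 1..16 (row-major over the 4x4 grid).  Returns the
    sorted cell ids and ``pi2 = 6/16``.
    """
    rng = _as_rng(rng)
    ncells = config.n_cells
    m = config.quadrant_segments_drawn
    if m > ncells:
        raise ValueError(f"cannot draw {m} cells from {ncells}")
    cells = sorted((rng.choice(ncells, size=m, replace=False) + 1).tolist())
    return cells, m / ncells


# ---------------------------------------------------------------------------
# Stage 3: households


@dataclass(frozen=True)
class SystematicSample:
    #: 1-based roster indices, in roster order
    indices: tuple[int, ...]
    interval: float
    start: float
    #: True when the roster was smaller than the quota (census fallback)
    shortfall: bool
    pi3: float


def systematic_sample_households(
    n_eligible: int,
    k: int,
    rng: np.random.Generator | int | None = None,
    start: float | None = None,
) -> SystematicSample:
    """Stage 3: fractional-interval systematic sampling from a roster.

    With roster size ``N`` and quota ``k`` the interval is ``I = N / k``; a
    random start ``u ~ Uniform(0, I]`` selects 1-based indices
    ``ceil(u + j I)`` for ``j = 0..k-1``.  This yields exactly ``min(k, N)``
    distinct indices and gives every roster entry inclusion probability
    ``k / N`` even when the interval is fractional.  If ``k >= N`` the whole
    roster is taken (a census) and a shortfall is flagged when ``N < k``.

    ``start`` forces the random start, for reproduction of a field draw.
    """
    if k <= 0:
        raise ValueError(f"quota k={k} must be >= 1")
    if n_eligible < 1:
        raise ValueError(f"roster size N={n_eligible} must be >= 1")
    rng = _as_rng(rng)
    if k >= n_eligible:
        return SystematicSample(
            indices=tuple(range(1, n_eligible + 1)),
            interval=1.0,
            start=1.0,
            shortfall=n_eligible < k,
            pi3=1.0,
        )
    interval = n_eligible / k
    if start is None:
        start = interval * (1.0 - float(rng.random()))  # uniform on (0, I]
    if not 0 < start <= interval:
        raise ValueError(f"start u={start} outside (0, {interval}]")
    indices = tuple(math.ceil(start + j * interval) for j in range(k))
    return SystematicSample(
        indices=indices,
        interval=interval,
        start=start,
        shortfall=False,
        pi3=k / n_eligible,
    )


def replace_absent_household(
    selected: Sequence[int],
    roster_size: int,
    absent_index: int,
) -> tuple[list[int], int | None]:
    """Replace an absent household with the next unselected roster entry.

    A household absent at three successive visits is replaced by the next
    not-yet-selected entry after it in the roster, wrapping to the roster
    start; if the roster is exhausted the slot stays unfilled (``None``).
    Returns the updated selection (roster order) and the replacement index.
    """
    if absent_index not in selected:
        raise ValueError(f"index {absent_index} is not currently selected")
    current = set(selected)
    for step in range(1, roster_size):
        candidate = (absent_index - 1 + step) % roster_size + 1
        if candidate not in current:
            new = sorted(current - {absent_index} | {candidate})
            return new, candidate
    return sorted(current - {absent_index}), None


# ---------------------------------------------------------------------------
# Composed plan


@dataclass
class SegmentPlan:
    """Third-stage selection within one selected segment (or pooled roster)."""

    segment: str
    roster_size: int
    selected: tuple[int, ...]
    start: float
    interval: float
    pi2: float
    pi3: float
    shortfall: bool
    #: roster entry ids (household identifiers) if known, parallel to 1..N
    roster: tuple[str, ...] | None = None


@dataclass
class AreaPlan:
    province: str
    health_zone: str
    health_area: str
    quota: int
    pi1: float
    segments: list[SegmentPlan] = field(default_factory=list)


@dataclass
class ZonePlan:
    province: str
    health_zone: str
    areas: list[AreaPlan] = field(default_factory=list)
    replacements: tuple[str, ...] = ()
    quota_inflated: bool = False


@dataclass
class SamplingPlan:
    """The realised three-stage selection with stage-wise probabilities."""

    config: DesignConfig
    seed: int | None
    zones: list[ZonePlan] = field(default_factory=list)

    def households(self) -> Iterator[dict]:
        """Yield one dict per selected household with its design weight."""
        for zp in self.zones:
            for ap in zp.areas:
                for sp in ap.segments:
                    for idx in sp.selected:
                        pi = ap.pi1 * sp.pi2 * sp.pi3
                        yield {
                            "province": ap.province,
                            "health_zone": zp.health_zone,
                            "health_area": ap.health_area,
                            "segment": sp.segment,
                            "household_index": idx,
                            "household": None if sp.roster is None else sp.roster[idx - 1],
                            "pi1": ap.pi1,
                            "pi2": sp.pi2,
                            "pi3": sp.pi3,
                            "weight": 1.0 / pi,
                        }

    @property
    def n_households(self) -> int:
        return sum(1 for _ in self.households())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": {**asdict(self.config), "quadrant_grid": list(self.config.quadrant_grid)},
            "seed": self.seed,
            "zones": [
                {
                    "province": zp.province,
                    "health_zone": zp.health_zone,
                    "replacements": list(zp.replacements),
                    "quota_inflated": zp.quota_inflated,
                    "areas": [
                        {
                            "health_area": ap.health_area,
                            "quota": ap.quota,
                            "pi1": ap.pi1,
                            "segments": [
                                {
                                    "segment": sp.segment,
                                    "roster_size": sp.roster_size,
                                    "selected": list(sp.selected),
                                    "start": sp.start,
                                    "interval": sp.interval,
                                    "pi2": sp.pi2,
                                    "pi3": sp.pi3,
                                    "shortfall": sp.shortfall,
                                    "roster": None if sp.roster is None else list(sp.roster),
                                }
                                for sp in ap.segments
                            ],
                        }
                        for ap in zp.areas
                    ],
                }
                for zp in self.zones
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SamplingPlan":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        cfg = dict(payload["config"])
        cfg["quadrant_grid"] = tuple(cfg["quadrant_grid"])
        config = DesignConfig(**cfg)
        plan = cls(config=config, seed=payload["seed"])
        for z in payload["zones"]:
            zp = ZonePlan(
                province=z.get("province", ""),
                health_zone=z["health_zone"],
                replacements=tuple(z["replacements"]),
                quota_inflated=z["quota_inflated"],
            )
            for a in z["areas"]:
                ap = AreaPlan(
                    province=z.get("province", ""),
                    health_zone=z["health_zone"],
                    health_area=a["health_area"],
                    quota=a["quota"],
                    pi1=a["pi1"],
                )
                for s in a["segments"]:
                    ap.segments.append(
                        SegmentPlan(
                            segment=s["segment"],
                            roster_size=s["roster_size"],
                            selected=tuple(s["selected"]),
                            start=s["start"],
                            interval=s["interval"],
                            pi2=s["pi2"],
                            pi3=s["pi3"],
                            shortfall=s["shortfall"],
                            roster=None if s["roster"] is None else tuple(s["roster"]),
                        )
                    )
                zp.areas.append(ap)
            plan.zones.append(zp)
        return plan


def _split_quota(quota: int, n_segments: int) -> list[int]:
    """Split an HA household quota across segments as evenly as possible."""
    base, extra = divmod(quota, n_segments)
    return [base + 1 if i < extra else base for i in range(n_segments)]


RosterProvider = Callable[[str, str, str, str | int], Sequence[str] | int]


def _default_roster(config: DesignConfig) -> RosterProvider:
    def provider(province: str, hz: str, ha: str, segment: str | int) -> int:
        return config.eligible_identified_per_segment

    return provider


def draw_survey_plan(
    frame: SamplingFrame,
    config: DesignConfig | None = None,
    rng: np.random.Generator | int | None = None,
    roster_provider: RosterProvider | None = None,
) -> SamplingPlan:
    """Compose the three sampling stages over every HZ of a frame.

    ``roster_provider(province, hz, ha, segment)`` supplies the eligible
    household roster (a list of ids, or just its size) for a selected
    segment; by default every segment yields
    ``config.eligible_identified_per_segment`` eligible households, the
    protocol's field stopping rule.  In the legacy protocol the third stage
    is one systematic draw per HA from the roster pooled across its selected
    segments (recorded as a single pooled ``SegmentPlan`` whose ``pi2`` is the
    segment-stage probability).
    """
    config = config or DesignConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    else:
        rng = _as_rng(rng)
    roster_provider = roster_provider or _default_roster(config)

    plan = SamplingPlan(config=config, seed=config.seed)
    for prov, hz in frame.iter_zones():
        psel = select_primary_units(hz, config, rng)
        zp = ZonePlan(
            province=prov.name,
            health_zone=hz.name,
            replacements=psel.replacements,
            quota_inflated=psel.quota_inflated,
        )
        areas_by_name = {a.name: a for a in hz.areas}
        for ha_name in psel.selected:
            ha = areas_by_name[ha_name]
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
                    roster = roster_provider(prov.name, hz.name, ha_name, cell)
                    n_roster, ids = _roster_size(roster)
                    draw = systematic_sample_households(n_roster, k, rng)
                    ap.segments.append(
                        SegmentPlan(
                            segment=f"Q{cell:02d}",
                            roster_size=n_roster,
                            selected=draw.indices,
                            start=draw.start,
                            interval=draw.interval,
                            pi2=pi2,
                            pi3=draw.pi3,
                            shortfall=draw.shortfall,
                            roster=ids,
                        )
                    )
            else:
                roster_names = ha.segments
                if roster_names is None:
                    raise ValueError(
                        f"health area {ha_name!r} has no segment roster; the legacy "
                        "protocol needs named segments (n_segments in the frame CSV)"
                    )
                segs, pi2 = segment_legacy(list(roster_names), config, rng)
                pooled_ids: list[str] = []
                pooled_n = 0
                for seg in segs:
                    roster = roster_provider(prov.name, hz.name, ha_name, seg)
                    n_roster, ids = _roster_size(roster)
                    pooled_n += n_roster
                    pooled_ids.extend(
                        ids if ids is not None else [f"{seg}-HH{i + 1:03d}" for i in range(n_roster)]
                    )
                draw = systematic_sample_households(pooled_n, psel.quota_per_ha, rng)
                if draw.shortfall:
                    warnings.warn(
                        f"{hz.name}/{ha_name}: pooled roster ({pooled_n}) smaller than "
                        f"quota ({psel.quota_per_ha}); enrolling all eligible households"
                    )
                ap.segments.append(
                    SegmentPlan(
                        segment="+".join(segs),
                        roster_size=pooled_n,
                        selected=draw.indices,
                        start=draw.start,
                        interval=draw.interval,
                        pi2=pi2,
                        pi3=draw.pi3,
                        shortfall=draw.shortfall,
                        roster=tuple(pooled_ids),
                    )
                )
            zp.areas.append(ap)
        plan.zones.append(zp)
    return plan


def _roster_size(roster: Sequence[str] | int) -> tuple[int, tuple[str, ...] | None]:
    if isinstance(roster, (int, np.integer)):
        return int(roster), None
    return len(roster), tuple(str(r) for r in roster)
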