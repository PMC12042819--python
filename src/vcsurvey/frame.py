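"""Sampling-frame and survey-record data model with CSV/JSON I/O.

The sampling frame mirrors the administrative layout of a decentralised
health system: provinces contain health zones (HZ, the district-equivalent
operational unit and the survey stratum), and each HZ is divided into health
areas (HA), each served by one health centre catering to roughly 5 000 to
10 000 people.  The HA is the primary sampling unit.

Two interchange formats are supported:

* CSV — one row per health area with columns ``province, health_zone,
  health_area, population, n_segments`` (the last two optional).  This is the
  canonical format; it matches DHIS2-style flat exports.
* JSON — the nested hierarchy, convenient for configuration-style use.

Child survey records are stored in a flat CSV with one row per child:
``province, health_zone, health_area, segment, household, child_id,
age_months`` followed by one column per antigen dose (``bcg1``, ``penta1`` …
``yellowfever1``) whose value names the evidence source (``card``,
``facility``, ``recall``) or ``none``.  Optional ``card_seen`` and ``weight``
columns carry home-based-record possession and the design weight.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd

__all__ = [
    "ANTIGEN_DOSES",
    "EVIDENCE_SOURCES",
    "ChildRecord",
    "Dose",
    "FrameSchemaError",
    "FrameValidationError",
    "FrameStatistics",
    "HealthArea",
    "HealthZone",
    "Province",
    "SamplingFrame",
    "frame_statistics",
    "read_child_records",
    "read_frame",
    "write_child_records",
    "write_frame",
]

#: Canonical antigen catalogue: antigen name -> number of scheduled doses.
#: Defines the dose columns of the child-record CSV; also the default
#: "fully vaccinated" schedule (BCG, 3x pentavalent, 3x pneumococcal
#: conjugate, 3x rotavirus, 3x oral polio, measles, yellow fever).
ANTIGEN_DOSES: dict[str, int] = {
    "BCG": 1,
    "Penta": 3,
    "PCV": 3,
    "Rota": 3,
    "OPV": 3,
    "Measles": 1,
    "YellowFever": 1,
}

#: Accepted evidence sources, strongest documentary value first.
EVIDENCE_SOURCES: tuple[str, ...] = ("card", "facility", "recall")

ELIGIBLE_AGE_RANGE: tuple[int, int] = (6, 23)


class FrameSchemaError(ValueError):
    """A frame or record file does not match the documented schema."""


class FrameValidationError(ValueError):
    """A structurally parseable frame violates a consistency rule."""


class Dose(NamedTuple):
    """One attested vaccine dose: ``(antigen, dose_number, source)``."""

    antigen: str
    dose_number: int
    source: str


@dataclass
class HealthArea:
    """A health area: the primary sampling unit (cluster).

    ``segments`` is the named street/village roster used by the legacy
    (2020–21) segmentation; the quadrant procedure needs no roster because it
    partitions the HA into an abstract 4x4 grid.
    """

    name: str
    population: int | None = None
    segments: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.population is not None:
            self.population = int(self.population)
            if self.population <= 0:
                raise FrameValidationError(
                    f"health area {self.name!r}: population must be a positive "
                    f"integer, got {self.population}"
                )
        if self.segments is not None:
            self.segments = tuple(self.segments)


@dataclass
class HealthZone:
    """A health zone: the survey stratum (district-equivalent unit)."""

    name: str
    areas: list[HealthArea] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.areas:
            raise FrameValidationError(f"health zone {self.name!r} has no health areas")
        names = [a.name for a in self.areas]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FrameValidationError(
                f"duplicate health area name(s) {dupes} in health zone {self.name!r}"
            )

    @property
    def n_areas(self) -> int:
        return len(self.areas)


@dataclass
class Province:
    name: str
    zones: list[HealthZone] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [z.name for z in self.zones]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FrameValidationError(
                f"duplicate health zone name(s) {dupes} in province {self.name!r}"
            )


@dataclass
class SamplingFrame:
    """The full province -> health zone -> health area hierarchy."""

    provinces: list[Province] = field(default_factory=list)

    def iter_zones(self) -> Iterator[tuple[Province, HealthZone]]:
        for prov in self.provinces:
            for zone in prov.zones:
                yield prov, zone

    @property
    def n_provinces(self) -> int:
        return len(self.provinces)

    @property
    def n_zones(self) -> int:
        return sum(len(p.zones) for p in self.provinces)

    @property
    def n_areas(self) -> int:
        return sum(z.n_areas for _, z in self.iter_zones())


@dataclass(frozen=True)
class ChildRecord:
    """One surveyed child with its dose evidence and design identifiers."""

    child_id: str
    province: str
    health_zone: str
    health_area: str
    segment: str
    household: str
    age_months: int
    doses: frozenset[Dose] = frozenset()
    card_seen: bool | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        lo, hi = ELIGIBLE_AGE_RANGE
        if not lo <= self.age_months <= hi:
            raise FrameValidationError(
                f"child {self.child_id!r}: age_months={self.age_months} outside "
                f"the eligible range [{lo}, {hi}]"
            )
        for d in self.doses:
            if d.dose_number < 1:
                raise FrameValidationError(
                    f"child {self.child_id!r}: dose number {d.dose_number} < 1"
                )
            if d.source not in EVIDENCE_SOURCES:
                raise FrameValidationError(
                    f"child {self.child_id!r}: unknown evidence source {d.source!r}"
                )


# ---------------------------------------------------------------------------
# Frame I/O


_FRAME_CSV_REQUIRED = ("province", "health_zone", "health_area")


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    return "csv"


def read_frame(path: str | Path, fmt: str | None = None) -> SamplingFrame:
    """Read a sampling frame from CSV (one HA per row) or nested JSON.

    Row order is preserved, so re-sorting health areas alphabetically during
    sampling is reproducible regardless of the order in the file.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        return _frame_from_dict(json.loads(path.read_text()))
    if fmt != "csv":
        raise ValueError(f"unknown frame format {fmt!r}")

    df = pd.read_csv(path, dtype={c: str for c in _FRAME_CSV_REQUIRED})
    missing = [c for c in _FRAME_CSV_REQUIRED if c not in df.columns]
    if missing:
        raise FrameSchemaError(
            f"frame CSV {path} is missing required column(s) {missing}; "
            f"expected at least {list(_FRAME_CSV_REQUIRED)}"
        )
    provinces: dict[str, dict[str, list[HealthArea]]] = {}
    for row in df.itertuples(index=False):
        pop = getattr(row, "population", None)
        if pop is not None and (pop == "" or (isinstance(pop, float) and math.isnan(pop))):
            pop = None
        nseg = getattr(row, "n_segments", None)
        segments = None
        if nseg is not None and not (isinstance(nseg, float) and math.isnan(nseg)):
            segments = tuple(f"{row.health_area}-S{i + 1:02d}" for i in range(int(nseg)))
        ha = HealthArea(
            name=str(row.health_area),
            population=None if pop is None else int(float(pop)),
            segments=segments,
        )
        provinces.setdefault(str(row.province), {}).setdefault(
            str(row.health_zone), []
        ).append(ha)
    return SamplingFrame(
        provinces=[
            Province(name=pname, zones=[HealthZone(name=z, areas=areas) for z, areas in zones.items()])
            for pname, zones in provinces.items()
        ]
    )


def _frame_from_dict(data: dict) -> SamplingFrame:
    try:
        provinces = []
        for p in data["provinces"]:
            zones = []
            for z in p["health_zones"]:
                areas = [
                    HealthArea(
                        name=a["name"],
                        population=a.get("population"),
                        segments=tuple(a["segments"]) if a.get("segments") else None,
                    )
                    for a in z["health_areas"]
                ]
                zones.append(HealthZone(name=z["name"], areas=areas))
            provinces.append(Province(name=p["name"], zones=zones))
    except (KeyError, TypeError) as exc:
        raise FrameSchemaError(f"frame JSON does not match the nested schema: {exc}") from exc
    return SamplingFrame(provinces=provinces)


def _frame_to_dict(frame: SamplingFrame) -> dict:
    return {
        "provinces": [
            {
                "name": p.name,
                "health_zones": [
                    {
                        "name": z.name,
                        "health_areas": [
                            {
                                "name": a.name,
                                **({"population": a.population} if a.population is not None else {}),
                                **({"segments": list(a.segments)} if a.segments is not None else {}),
                            }
                            for a in z.areas
                        ],
                    }
                    for z in p.zones
                ],
            }
            for p in frame.provinces
        ]
    }


def write_frame(frame: SamplingFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a sampling frame to CSV or JSON (inverse of :func:`read_frame`)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        path.write_text(json.dumps(_frame_to_dict(frame), indent=2))
        return
    rows = []
    for prov in frame.provinces:
        for zone in prov.zones:
            for area in zone.areas:
                rows.append(
                    {
                        "province": prov.name,
                        "health_zone": zone.name,
                        "health_area": area.name,
                        "population": area.population,
                        "n_segments": None if area.segments is None else len(area.segments),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Frame statistics

#: HA-count bands used in frame summaries: (label, low, high inclusive).
#: The last band is open-ended so the bands always partition the HZ set.
_HA_BANDS: tuple[tuple[str, int, float], ...] = (
    ("<=10", 0, 10),
    ("11-20", 11, 20),
    ("21-25", 21, 25),
    ("26-30", 26, 30),
    ("31-41", 31, math.inf),
)


@dataclass(frozen=True)
class FrameStatistics:
    n_provinces: int
    n_zones: int
    n_areas: int
    mean_areas_per_zone: float
    median_areas_per_zone: float
    min_areas_per_zone: int
    max_areas_per_zone: int
    band_counts: dict[str, int]


def frame_statistics(frame: SamplingFrame) -> FrameStatistics:
    """Summarise per-HZ health-area counts (mean/median/min/max and bands)."""
    counts = [z.n_areas for _, z in frame.iter_zones()]
    if not counts:
        raise FrameValidationError("cannot summarise an empty frame")
    s = pd.Series(counts)
    bands = {
        label: int(((s >= lo) & (s <= hi)).sum()) for label, lo, hi in _HA_BANDS
    }
    return FrameStatistics(
        n_provinces=frame.n_provinces,
        n_zones=frame.n_zones,
        n_areas=frame.n_areas,
        mean_areas_per_zone=float(s.mean()),
        median_areas_per_zone=float(s.median()),
        min_areas_per_zone=int(s.min()),
        max_areas_per_zone=int(s.max()),
        band_counts=bands,
    )


# ---------------------------------------------------------------------------
# Child-record I/O


def _dose_columns() -> list[tuple[str, str, int]]:
    """(column name, antigen, dose number) for every catalogued dose."""
    cols = []
    for antigen, n in ANTIGEN_DOSES.items():
        for k in range(1, n + 1):
            cols.append((f"{antigen.lower()}{k}", antigen, k))
    return cols


def write_child_records(records: Iterable[ChildRecord], path: str | Path) -> None:
    """Write child records to the flat survey CSV schema."""
    dose_cols = _dose_columns()
    by_key = {(a.lower(), k): col for col, a, k in dose_cols}
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "province": rec.province,
            "health_zone": rec.health_zone,
            "health_area": rec.health_area,
            "segment": rec.segment,
            "household": rec.household,
            "child_id": rec.child_id,
            "age_months": rec.age_months,
        }
        for col, _, _ in dose_cols:
            row[col] = "none"
        for d in rec.doses:
            key = (d.antigen.lower(), d.dose_number)
            if key not in by_key:
                raise FrameSchemaError(
                    f"child {rec.child_id!r}: dose {d.antigen}{d.dose_number} has no "
                    f"column in the record schema (known antigens: "
                    f"{sorted(ANTIGEN_DOSES)})"
                )
            row[by_key[key]] = d.source
        if rec.card_seen is not None:
            row["card_seen"] = int(rec.card_seen)
        if rec.weight is not None:
            row["weight"] = rec.weight
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_child_records(path: str | Path) -> list[ChildRecord]:
    """Read child records from the flat survey CSV schema."""
    df = pd.read_csv(path)
    required = [
        "province",
        "health_zone",
        "health_area",
        "segment",
        "household",
        "child_id",
        "age_months",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FrameSchemaError(f"child-record CSV {path} missing column(s) {missing}")
    dose_cols = [(col, a, k) for col, a, k in _dose_columns() if col in df.columns]
    records = []
    for row in df.to_dict("records"):
        doses = set()
        for col, antigen, k in dose_cols:
            val = row[col]
            if isinstance(val, float) and math.isnan(val):
                continue
            val = str(val).strip().lower()
            if val in ("", "none"):
                continue
            if val not in EVIDENCE_SOURCES:
                raise FrameSchemaError(
                    f"child {row['child_id']!r}: column {col!r} has value {val!r}; "
                    f"expected one of {EVIDENCE_SOURCES + ('none',)}"
                )
            doses.add(Dose(antigen, k, val))
        card_seen = row.get("card_seen")
        if card_seen is not None and not (isinstance(card_seen, float) and math.isnan(card_seen)):
            card_seen = bool(int(card_seen))
        else:
            card_seen = None
        weight = row.get("weight")
        if weight is not None and not (isinstance(weight, float) and math.isnan(weight)):
            weight = float(weight)
        else:
            weight = None
        records.append(
            ChildRecord(
                child_id=str(row["child_id"]),
                province=str(row["province"]),
                health_zone=str(row["health_zone"]),
                health_area=str(row["health_area"]),
                segment=str(row["segment"]),
                household=str(row["household"]),
                age_months=int(row["age_months"]),
                doses=frozenset(doses),
                card_seen=card_seen,
                weight=weight,
            )
        )
    return records
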