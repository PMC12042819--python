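"""Per-child vaccination indicators and cohort groupings.

Indicators follow the crude (dose-possession) convention: a dose counts if
any evidence source attests it — home-based record (card), a facility
register found by traceback, or caregiver recall.  The headline indicators
are:

* **card possession** — a home-based record was seen for the child,
  regardless of its completeness;
* **zero dose** — the child has received no dose of a pentavalent
  (DTP-HepB-Hib) vaccine, from any source;
* **pentavalent 1 / 3, measles** — possession of the named dose;
* **fully vaccinated** — possession of every dose of the schedule (BCG,
  three pentavalent, three pneumococcal conjugate, three rotavirus, three
  oral polio, measles, yellow fever).

Results are reported separately for the 6–11 and 12–23 month cohorts.
Timeliness (doses received before the first birthday) requires dose dates
and is available only as the optional ``by_age_12m`` hook, off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from vcsurvey.frame import ANTIGEN_DOSES, EVIDENCE_SOURCES, ChildRecord, Dose

__all__ = [
    "DEFAULT_SCHEDULE",
    "IndicatorResult",
    "assign_cohort",
    "compute_indicators",
    "fully_vaccinated",
    "has_dose",
    "indicator_table",
    "resolve_evidence",
    "zero_dose",
]

#: antigen -> dose count required for "fully vaccinated"
DEFAULT_SCHEDULE: dict[str, int] = dict(ANTIGEN_DOSES)

#: Documentary precedence when several sources attest the same dose.
_SOURCE_RANK = {src: rank for rank, src in enumerate(EVIDENCE_SOURCES)}

COHORT_6_11 = "6-11"
COHORT_12_23 = "12-23"


def resolve_evidence(raw_doses: Iterable[Dose]) -> dict[tuple[str, int], str]:
    """Consolidate raw dose reports into one source per (antigen, dose).

    When the same dose is attested by several sources the strongest one is
    kept (card > facility > recall); a dose counts if *any* source attests
    it.  Unknown antigen names are rejected with the accepted list.
    """
    consolidated: dict[tuple[str, int], str] = {}
    for dose in raw_doses:
        if dose.antigen not in ANTIGEN_DOSES:
            raise ValueError(
                f"unknown antigen {dose.antigen!r}; accepted names: "
                f"{sorted(ANTIGEN_DOSES)}"
            )
        if dose.source not in _SOURCE_RANK:
            raise ValueError(
                f"unknown evidence source {dose.source!r}; accepted: {EVIDENCE_SOURCES}"
            )
        key = (dose.antigen, dose.dose_number)
        if key not in consolidated or _SOURCE_RANK[dose.source] < _SOURCE_RANK[consolidated[key]]:
            consolidated[key] = dose.source
    return consolidated


def has_dose(doses: Mapping[tuple[str, int], str] | Iterable[Dose], antigen: str, dose_number: int) -> bool:
    """True if the consolidated evidence contains the given dose."""
    if not isinstance(doses, Mapping):
        doses = resolve_evidence(doses)
    return (antigen, dose_number) in doses


def zero_dose(doses: Mapping[tuple[str, int], str] | Iterable[Dose]) -> bool:
    """True iff the child has no pentavalent dose of any number, any source."""
    if not isinstance(doses, Mapping):
        doses = resolve_evidence(doses)
    return not any(antigen == "Penta" for antigen, _ in doses)


def fully_vaccinated(
    doses: Mapping[tuple[str, int], str] | Iterable[Dose],
    schedule: Mapping[str, int] = DEFAULT_SCHEDULE,
) -> bool:
    """True iff the child possesses doses 1..required for every antigen."""
    if not isinstance(doses, Mapping):
        doses = resolve_evidence(doses)
    if not schedule:
        warnings.warn("empty schedule: fully_vaccinated is vacuously true")
        return True
    return all(
        (antigen, k) in doses
        for antigen, required in schedule.items()
        for k in range(1, required + 1)
    )


def assign_cohort(age_months: int) -> str:
    """Split eligible ages into the 6–11 and 12–23 month reporting cohorts."""
    if not 6 <= age_months <= 23:
        raise ValueError(f"age_months={age_months} outside the eligible range [6, 23]")
    return COHORT_6_11 if age_months <= 11 else COHORT_12_23


@dataclass(frozen=True)
class IndicatorResult:
    child_id: str
    cohort: str
    card_possession: bool
    zero_dose: bool
    penta1: bool
    penta3: bool
    measles: bool
    fully_vaccinated: bool


def compute_indicators(
    record: ChildRecord,
    schedule: Mapping[str, int] = DEFAULT_SCHEDULE,
) -> IndicatorResult:
    """Evaluate every headline indicator for one child record.

    Card possession reflects only whether a home-based record was seen
    (``record.card_seen``); when that flag is absent it falls back to
    whether any dose is card-attested.
    """
    doses = resolve_evidence(record.doses)
    if record.card_seen is not None:
        card = record.card_seen
    else:
        card = any(src == "card" for src in doses.values())
    return IndicatorResult(
        child_id=record.child_id,
        cohort=assign_cohort(record.age_months),
        card_possession=card,
        zero_dose=zero_dose(doses),
        penta1=has_dose(doses, "Penta", 1),
        penta3=has_dose(doses, "Penta", 3),
        measles=has_dose(doses, "Measles", 1),
        fully_vaccinated=fully_vaccinated(doses, schedule),
    )


def indicator_table(
    records: Iterable[ChildRecord],
    schedule: Mapping[str, int] = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Per-child indicator table ready for design-based estimation.

    Columns: the design identifiers (province, health_zone, health_area,
    segment, household), the design weight (1.0 when the record carries
    none), age/cohort, and one boolean column per indicator.
    """
    rows = []
    for rec in records:
        ind = compute_indicators(rec, schedule)
        rows.append(
            {
                "province": rec.province,
                "health_zone": rec.health_zone,
                "health_area": rec.health_area,
                "segment": rec.segment,
                "household": rec.household,
                "child_id": rec.child_id,
                "age_months": rec.age_months,
                "cohort": ind.cohort,
                "weight": 1.0 if rec.weight is None else rec.weight,
                "card_possession": ind.card_possession,
                "zero_dose": ind.zero_dose,
                "penta1": ind.penta1,
                "penta3": ind.penta3,
                "measles": ind.measles,
                "fully_vaccinated": ind.fully_vaccinated,
            }
        )
    return pd.DataFrame(rows)
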