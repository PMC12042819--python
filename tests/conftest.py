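import numpy as np
import pytest

from vcsurvey.frame import ChildRecord, Dose, HealthArea, HealthZone, Province, SamplingFrame


def make_frame(n_areas: int = 18, n_zones: int = 1, n_provinces: int = 1,
               n_segments: int | None = None) -> SamplingFrame:
    provinces = []
    for p in range(n_provinces):
        zones = []
        for z in range(n_zones):
            areas = [
                HealthArea(
                    name=(ha_name := f"P{p + 1}Z{z + 1}A{a + 1:02d}"),
                    population=6000,
                    segments=None if n_segments is None else tuple(
                        f"{ha_name}-S{s + 1:02d}" for s in range(n_segments)
                    ),
                )
                for a in range(n_areas)
            ]
            zones.append(HealthZone(name=f"P{p + 1}Z{z + 1}", areas=areas))
        provinces.append(Province(name=f"P{p + 1}", zones=zones))
    return SamplingFrame(provinces=provinces)


@pytest.fixture
def single_hz_frame() -> SamplingFrame:
    """One province, one HZ with 18 alphabetically named HAs."""
    return make_frame(n_areas=18)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_child(child_id="c1", doses=(), age=14, ha="A1", segment="Q01",
               household="H1", card_seen=None, weight=None) -> ChildRecord:
    return ChildRecord(
        child_id=child_id,
        province="P1",
        health_zone="Z1",
        health_area=ha,
        segment=segment,
        household=household,
        age_months=age,
        doses=frozenset(Dose(*d) for d in doses),
        card_seen=card_seen,
        weight=weight,
    )
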