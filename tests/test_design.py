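"""Sample-size formula and the three sampling stages."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_frame
from vcsurvey.design import (
    MICS_2018_PROVINCES,
    DesignConfig,
    SampleSizeSpec,
    SamplingPlan,
    draw_survey_plan,
    min_sample_size,
    replace_absent_household,
    segment_legacy,
    segment_quadrant,
    select_primary_units,
    systematic_sample_households,
)

# Printed per-province minimums (1 decimal) for the standard inputs
# deff=1.5, Z=1.96, d=10 and the MICS-2018 anticipated coverages.
EXPECTED_MIN_SAMPLE = {
    "Haut-Katanga": 142.9, "Haut-Lomami": 132.3, "Kasai Central": 139.7,
    "Kasai Oriental": 115.9, "Kasai": 69.0, "Kinshasa": 140.3,
    "Kongo Central": 143.8, "Kwango": 78.6, "Kwilu": 70.6, "Lomami": 113.3,
    "Ituri": 138.3, "Maniema": 35.5, "Mongala": 43.4, "Sankuru": 14.6,
    "Sud Kivu": 144.0, "Tanganyika": 96.3, "Tshopo": 94.6, "Lualaba": 95.9,
    "Maindombe": 60.4, "Bas-Uele": 104.5, "Haut-Uele": 83.2,
    "Nord-Kivu": 94.9, "Sud-Ubangi": 113.3, "Nord-Ubangi": 79.8,
    "Equateur": 117.4, "Tshuapa": 75.1,
}


@pytest.mark.parametrize("province,p", sorted(MICS_2018_PROVINCES.items()))
def test_min_sample_size_reproduces_published_table(province, p):
    result = min_sample_size(SampleSizeSpec(deff=1.5, z=1.96, p=p, d=10.0))
    assert result.reported == EXPECTED_MIN_SAMPLE[province]


def test_min_sample_size_edge_cases():
    assert min_sample_size(SampleSizeSpec(p=0.0)).reported == 0.0
    assert min_sample_size(SampleSizeSpec(p=100.0)).reported == 0.0
    assert min_sample_size(SampleSizeSpec(deff=1.0, p=50.0)).reported == 96.0


def test_invalid_spec_rejected():
    with pytest.raises(ValueError, match=r"\[0, 100\]"):
        SampleSizeSpec(p=101.0)
    with pytest.raises(ValueError, match="margin"):
        SampleSizeSpec(d=0.0)


@settings(derandomize=True, max_examples=100)
@given(p=st.floats(0.0, 100.0))
def test_min_sample_size_symmetric_and_maximal_at_half(p):
    spec = SampleSizeSpec(p=p)
    mirrored = SampleSizeSpec(p=100.0 - p)
    assert min_sample_size(spec).raw == pytest.approx(min_sample_size(mirrored).raw)
    assert min_sample_size(spec).raw <= min_sample_size(SampleSizeSpec(p=50.0)).raw + 1e-9
    assert min_sample_size(spec).operational >= min_sample_size(spec).raw


# ---------------------------------------------------------------------------
# Stage 1


def test_primary_selection_standard_hz(single_hz_frame, rng):
    hz = single_hz_frame.provinces[0].zones[0]
    sel = select_primary_units(hz, DesignConfig(), rng)
    assert len(sel.selected) == 5 and len(sel.replacements) == 2
    assert len(set(sel.selected) | set(sel.replacements)) == 7
    assert sel.pi1 == pytest.approx(5 / 18)
    assert sel.quota_per_ha == 30 and not sel.quota_inflated


def test_primary_selection_small_hz_takes_all_and_inflates_quota(rng):
    hz = make_frame(n_areas=4).provinces[0].zones[0]
    sel = select_primary_units(hz, DesignConfig(), rng)
    assert len(sel.selected) == 4 and not sel.replacements
    assert sel.quota_per_ha == 38  # ceil(5 * 30 / 4)
    assert sel.pi1 == 1.0 and sel.quota_inflated


def test_primary_selection_boundary_five_areas(rng):
    hz = make_frame(n_areas=5).provinces[0].zones[0]
    sel = select_primary_units(hz, DesignConfig(), rng)
    assert len(sel.selected) == 5 and sel.pi1 == 1.0 and not sel.quota_inflated


def test_primary_selection_equal_probability():
    hz = make_frame(n_areas=10).provinces[0].zones[0]
    rng = np.random.default_rng(8)
    counts = {a.name: 0 for a in hz.areas}
    n_draws = 600
    for _ in range(n_draws):
        for name in select_primary_units(hz, DesignConfig(), rng).selected:
            counts[name] += 1
    expected = 5 / 10
    tol = 3 * math.sqrt(expected * (1 - expected) / n_draws)
    for name, c in counts.items():
        assert abs(c / n_draws - expected) < tol, name


# ---------------------------------------------------------------------------
# Stage 2


@pytest.mark.parametrize("n,expected_m", [(10, 3), (7, 3), (1, 1)])
def test_legacy_segment_counts(n, expected_m, rng):
    roster = [f"S{i}" for i in range(n)]
    selected, pi2 = segment_legacy(roster, DesignConfig(protocol="legacy2020"), rng)
    assert len(selected) == len(set(selected)) == expected_m
    assert pi2 == pytest.approx(expected_m / n)


def test_legacy_empty_roster_rejected(rng):
    with pytest.raises(ValueError, match="empty"):
        segment_legacy([], DesignConfig(protocol="legacy2020"), rng)


def test_quadrant_draws_six_distinct_cells(rng):
    cells, pi2 = segment_quadrant(DesignConfig(), rng)
    assert len(cells) == len(set(cells)) == 6
    assert all(1 <= c <= 16 for c in cells)
    assert pi2 == pytest.approx(0.375)


def test_quadrant_deterministic_under_seed():
    a, _ = segment_quadrant(DesignConfig(), np.random.default_rng(3))
    b, _ = segment_quadrant(DesignConfig(), np.random.default_rng(3))
    assert a == b


def test_quadrant_cell_frequencies_uniform():
    rng = np.random.default_rng(17)
    n_draws = 10_000
    counts = np.zeros(16)
    cfg = DesignConfig()
    for _ in range(n_draws):
        cells, _ = segment_quadrant(cfg, rng)
        for c in cells:
            counts[c - 1] += 1
    freq = counts / n_draws
    tol = 3 * math.sqrt(0.375 * 0.625 / n_draws)
    assert np.all(np.abs(freq - 0.375) < tol)


def test_inconsistent_quadrant_config_rejected():
    with pytest.raises(ValueError, match="cannot draw"):
        DesignConfig(quadrant_grid=(2, 2), quadrant_segments_drawn=6,
                     households_per_segment=5, households_per_ha=30)


# ---------------------------------------------------------------------------
# Stage 3


def test_systematic_integer_interval():
    s = systematic_sample_households(15, 5, start=2.0)
    assert s.indices == (2, 5, 8, 11, 14)
    assert s.pi3 == pytest.approx(1 / 3)


def test_systematic_fractional_interval():
    s = systematic_sample_households(18, 5, start=0.5)
    assert s.indices == (1, 5, 8, 12, 15)


def test_systematic_census_case():
    s = systematic_sample_households(5, 5)
    assert s.indices == (1, 2, 3, 4, 5) and not s.shortfall
    short = systematic_sample_households(3, 5)
    assert short.indices == (1, 2, 3) and short.shortfall and short.pi3 == 1.0


@settings(derandomize=True, max_examples=200)
@given(n=st.integers(1, 60), k=st.integers(1, 40), seed=st.integers(0, 2**16))
def test_systematic_always_min_k_n_distinct(n, k, seed):
    s = systematic_sample_households(n, k, np.random.default_rng(seed))
    assert len(s.indices) == len(set(s.indices)) == min(k, n)
    assert all(1 <= i <= n for i in s.indices)


def test_systematic_inclusion_probability_by_enumeration():
    # sweep the random start over a fine grid of (0, I]: every roster entry
    # must be selected in a fraction k/N of the sweeps
    n, k = 7, 3
    interval = n / k
    grid = np.linspace(1e-9, interval, 20_001)
    counts = np.zeros(n)
    for u in grid:
        for i in systematic_sample_households(n, k, start=float(u)).indices:
            counts[i - 1] += 1
    freq = counts / grid.size
    assert np.all(np.abs(freq - k / n) < 1e-3)


def test_replace_absent_household_next_in_roster():
    updated, repl = replace_absent_household([2, 5, 8, 11, 14], 15, 5)
    assert updated == [2, 6, 8, 11, 14] and repl == 6
    updated, repl = replace_absent_household([2, 5, 8, 11, 14], 15, 14)
    assert repl == 15 and 15 in updated
    # full census: no unselected entries remain
    updated, repl = replace_absent_household([1, 2, 3], 3, 2)
    assert repl is None and updated == [1, 3]
    with pytest.raises(ValueError, match="not currently selected"):
        replace_absent_household([1, 2], 5, 4)


# ---------------------------------------------------------------------------
# Composed plan


def test_plan_quadrant_household_arithmetic(single_hz_frame):
    plan = draw_survey_plan(single_hz_frame, DesignConfig(seed=11))
    assert plan.n_households == 150  # 5 HAs x 6 segments x 5 households
    households = list(plan.households())
    weights = {round(h["weight"], 10) for h in households}
    assert weights == {round(1 / ((5 / 18) * (6 / 16) * (5 / 15)), 10)}
    assert households[0]["weight"] == pytest.approx(28.8)
    for h in households:
        pi = h["pi1"] * h["pi2"] * h["pi3"]
        assert 0 < pi <= 1


def test_plan_legacy_uses_pooled_roster():
    frame = make_frame(n_areas=18, n_segments=10)
    plan = draw_survey_plan(frame, DesignConfig(protocol="legacy2020", seed=4))
    ap = plan.zones[0].areas[0]
    seg = ap.segments[0]
    assert seg.pi2 == pytest.approx(0.3)
    assert seg.roster_size == 45  # 3 segments x 15 eligible
    assert len(seg.selected) == 30
    assert seg.pi3 == pytest.approx(30 / 45)


def test_plan_json_round_trip(single_hz_frame, tmp_path):
    plan = draw_survey_plan(single_hz_frame, DesignConfig(seed=21))
    path = tmp_path / "plan.json"
    plan.to_json(path)
    reread = SamplingPlan.from_json(path)
    assert reread.config == plan.config
    assert reread.n_households == plan.n_households
    assert [list(h.values())[:6] for h in reread.households()] == [
        list(h.values())[:6] for h in plan.households()
    ]
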