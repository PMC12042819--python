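"""Design-based estimators against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from vcsurvey.estimate import (
    clustered_variance,
    confidence_interval,
    design_effect,
    estimate_coverage,
    icc_from_deff,
    weighted_proportion,
)


def oracle_variance(y, w, cluster, stratum):
    """Textbook stratified ultimate-cluster variance, written with plain loops."""
    y = list(map(float, y))
    w = list(map(float, w))
    total_weight = sum(w)
    p = sum(wi * yi for wi, yi in zip(w, y)) / total_weight
    variance = 0.0
    for h in sorted(set(stratum)):
        cluster_totals = []
        for c in sorted({ci for ci, hi in zip(cluster, stratum) if hi == h}):
            z = sum(
                wi * (yi - p)
                for yi, wi, ci, hi in zip(y, w, cluster, stratum)
                if hi == h and ci == c
            )
            cluster_totals.append(z)
        n_h = len(cluster_totals)
        if n_h < 2:
            continue
        zbar = sum(cluster_totals) / n_h
        variance += n_h / (n_h - 1) * sum((z - zbar) ** 2 for z in cluster_totals)
    return variance / total_weight**2


def random_toy_dataset(rng):
    """<= 4 strata x <= 3 clusters x <= 10 children, random weights."""
    rows = []
    for h in range(rng.integers(2, 5)):
        for c in range(rng.integers(2, 4)):
            for _ in range(rng.integers(2, 11)):
                rows.append(
                    {
                        "stratum": f"h{h}",
                        "cluster": f"h{h}c{c}",
                        "y": float(rng.random() < 0.6),
                        "w": float(rng.uniform(0.5, 40.0)),
                    }
                )
    return pd.DataFrame(rows)


def test_weighted_proportion_examples():
    assert weighted_proportion([1] * 15 + [0] * 15, [1.0] * 30) == pytest.approx(50.0)
    assert weighted_proportion([1, 1, 1], [0.2, 5.0, 9.9]) == pytest.approx(100.0)
    assert weighted_proportion([1, 0, 0], [1, 1, 2]) == pytest.approx(25.0)
    with pytest.raises(ValueError, match="empty"):
        weighted_proportion([], [])


def test_variance_zero_when_clusters_identical():
    y = [1, 0, 1, 0]
    v = clustered_variance(y, [1.0] * 4, ["a", "a", "b", "b"])
    assert v == pytest.approx(0.0, abs=1e-15)


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_variance_matches_bruteforce_oracle(seed):
    df = random_toy_dataset(np.random.default_rng(seed))
    ours = clustered_variance(df.y, df.w, df.cluster, df.stratum)
    oracle = oracle_variance(df.y, df.w, df.cluster, df.stratum)
    assert ours == pytest.approx(oracle, rel=1e-10)


def test_variance_invariant_to_weight_rescaling():
    df = random_toy_dataset(np.random.default_rng(7))
    v1 = clustered_variance(df.y, df.w, df.cluster, df.stratum)
    v2 = clustered_variance(df.y, 2.0 * df.w, df.cluster, df.stratum)
    assert v1 == pytest.approx(v2, rel=1e-12)


def test_singleton_cluster_treated_as_certainty_unit():
    with pytest.warns(UserWarning, match="single"):
        v = clustered_variance([1, 0, 1], [1, 1, 1], ["a", "a", "a"])
    assert v == 0.0


def test_design_effect_and_icc_closed_forms():
    df = random_toy_dataset(np.random.default_rng(11))
    deff = design_effect(df.y, df.w, df.cluster, df.stratum)
    p = float(np.sum(df.w * df.y) / np.sum(df.w))
    v_srs = p * (1 - p) / (len(df) - 1)
    assert deff == pytest.approx(
        oracle_variance(df.y, df.w, df.cluster, df.stratum) / v_srs, rel=1e-10
    )
    assert icc_from_deff(1.5, 30.0) == pytest.approx(0.017241, abs=5e-7)
    assert icc_from_deff(1.0, 30.0) == 0.0
    assert np.isnan(design_effect([1, 1], [1, 1], ["a", "b"]))


def test_wilson_interval_examples():
    lo, hi = confidence_interval(0.0, 50)
    assert lo == 0.0
    lo, hi = confidence_interval(50.0, 100)
    assert (round(lo, 2), round(hi, 2)) == (40.38, 59.62)


@settings(derandomize=True, max_examples=100)
@given(p=st.floats(0.0, 100.0), n=st.floats(2.0, 5000.0))
def test_wilson_matches_statsmodels(p, n):
    lo, hi = confidence_interval(p, n)
    sm_lo, sm_hi = proportion_confint(p / 100 * n, n, alpha=0.05, method="wilson")
    assert lo == pytest.approx(100 * sm_lo, abs=1e-8)
    assert hi == pytest.approx(100 * sm_hi, abs=1e-8)


def test_wilson_width_monotone_in_effective_n():
    widths = [
        np.diff(confidence_interval(37.0, n))[0] for n in (10, 40, 160, 640)
    ]
    assert all(a > b for a, b in zip(widths, widths[1:]))


def test_interval_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="effective"):
        confidence_interval(50.0, 0.5)


def make_table(rng, n_hz=2, coverage=None):
    rows = []
    for z in range(n_hz):
        cov = coverage if coverage is not None else rng.uniform(0.3, 0.8)
        for c in range(3):
            for i in range(8):
                rows.append(
                    {
                        "province": "P1",
                        "health_zone": f"Z{z}",
                        "health_area": f"Z{z}A{c}",
                        "weight": float(rng.uniform(1, 30)),
                        "cohort": "12-23",
                        "covered": float(rng.random() < cov),
                    }
                )
    return pd.DataFrame(rows)


def test_equal_weights_single_cluster_reduces_to_naive_proportion():
    df = pd.DataFrame(
        {
            "province": "P1",
            "health_zone": "Z1",
            "health_area": "A1",
            "weight": 1.0,
            "covered": [1.0, 0.0, 1.0, 1.0],
        }
    )
    with pytest.warns(UserWarning):
        est = estimate_coverage(df, ["covered"], level="hz").iloc[0]
    assert est["estimate"] == pytest.approx(75.0)


def test_province_pooling_invariant_when_hz_coverages_equal():
    df = make_table(np.random.default_rng(3), n_hz=2)
    df["all_pos"] = 1.0
    est = estimate_coverage(df, ["all_pos"], level="province").iloc[0]
    assert est["estimate"] == pytest.approx(100.0)


def test_province_estimate_matches_stratified_oracle():
    df = make_table(np.random.default_rng(9), n_hz=2)
    est = estimate_coverage(df, ["covered"], level="province").iloc[0]
    p_oracle = 100 * float(np.sum(df.weight * df.covered) / np.sum(df.weight))
    assert est["estimate"] == pytest.approx(p_oracle, rel=1e-12)
    strata = list(df["health_zone"])
    clusters = list(df["health_area"])
    v_oracle = oracle_variance(df.covered, df.weight, clusters, strata)
    deff = est["deff"]
    p = p_oracle / 100
    v_srs = p * (1 - p) / (len(df) - 1)
    assert deff == pytest.approx(v_oracle / v_srs, rel=1e-10)


def test_national_estimate_inside_hz_range():
    df = make_table(np.random.default_rng(15), n_hz=4)
    hz = estimate_coverage(df, ["covered"], level="hz")
    nat = estimate_coverage(df, ["covered"], level="national").iloc[0]
    assert hz["estimate"].min() - 1e-9 <= nat["estimate"] <= hz["estimate"].max() + 1e-9


def test_estimate_bounds_and_effective_n():
    df = make_table(np.random.default_rng(21), n_hz=3)
    for _, est in estimate_coverage(df, ["covered"], level="hz").iterrows():
        assert 0 <= est["ci_low"] <= est["estimate"] <= est["ci_high"] <= 100
        assert est["n_eff"] <= est["n"] + 1e-9
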