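"""Growth-standard engine: family math, monotonicity, inverses, exclusions."""

import numpy as np
import pytest
from scipy.stats import norm

from epwscreen.errors import (
    MissingCovariateError,
    ParameterError,
    RangeError,
    ValidationError,
)
from epwscreen.standards import (
    CustomizationParams,
    QuantileGrid,
    ZscoreCurveParams,
    epw_all_standards,
    epw_customized,
    epw_quantile_grid,
    epw_table,
    epw_zscore,
    exclusion_tally,
    load_default_standards,
    standard_from_dict,
)
from epwscreen.synthetic_cohort import CohortConfig, generate_cohort

GA = np.arange(238, 259)


def _flat_curve(median=2500.0, sigma=0.11, transform="log", shift=0.0):
    return ZscoreCurveParams(
        ga_days=GA, median_g=np.full(GA.size, median), sigma=sigma, transform=transform,
        shift_frac=shift,
    )


def _grid(scale=1.0):
    levels = np.array([5, 10, 25, 50, 75, 90, 95], dtype=float)
    base = 2500.0 * np.exp(0.11 * norm.ppf(levels / 100.0))
    ga = np.array([238, 245, 252, 259])
    weights = np.outer(scale * np.exp(0.01 * (ga - 246)), base)
    return QuantileGrid(ga_days=ga, weights_g=weights)


def test_median_weight_maps_to_percentile_50():
    pct, z = epw_zscore(2500.0, 246, _flat_curve())
    assert float(pct) == pytest.approx(50.0, abs=1e-9)
    assert float(z) == pytest.approx(0.0, abs=1e-12)


def test_untransformed_normal_p90():
    """EFW = median*(1 + 1.2816*CV) sits at the 90th percentile."""
    cv = 0.09
    params = _flat_curve(sigma=cv, transform="normal")
    pct, _ = epw_zscore(2500.0 * (1 + norm.ppf(0.9) * cv), 246, params)
    assert float(pct) == pytest.approx(90.0, abs=0.1)


def test_percentile_strictly_monotone_in_efw_all_standards(registry, cohort):
    """Across all six bundled specs, percentile rises strictly with EFW over
    the span where the percentile scale is interior (unclamped)."""
    frame = cohort[0].iloc[[0]]
    probe_p = np.linspace(0.5, 99.5, 100)
    for sid, spec in registry.items():
        profile = {c: frame.iloc[0][c] for c in spec.customization_covariates} or None
        weights = np.asarray(spec.weight_at_percentile(probe_p, 246, profile))
        assert np.all(np.diff(weights) > 0), sid
        pct = np.asarray(spec.percentile(weights, np.full(100, 246), profile)[0])
        assert np.all(np.diff(pct) > 0), sid


def test_ga_envelope_enforced(registry):
    with pytest.raises(RangeError):
        epw_zscore(2500.0, 300, registry["msuh_nc"].params)


def test_nonpositive_efw_rejected(registry):
    with pytest.raises(ValidationError):
        epw_zscore(-10.0, 246, registry["msuh_nc"].params)


# ---------------------------------------------------------------------------
# customization


def _cust_params(sigma=0.11):
    return CustomizationParams(
        base_term_weight=3500.0,
        reference_ga_days=280,
        prop_rate_per_day=0.01,
        covariate_effects={
            "maternal_height_cm": {"per_unit": 8.0, "reference": 163.0},
            "fetal_sex": {"categories": {"male": 60.0, "female": -60.0}},
        },
        sigma=sigma,
        transform="log",
    )


REF_PROFILE = {"maternal_height_cm": 163.0, "fetal_sex": "reference"}


def test_reference_mother_neutrality():
    """With all effects zero, the customized percentile equals the plain
    z-score percentile whose median curve is base*proportionality."""
    params = _cust_params()
    profile = {"maternal_height_cm": 163.0, "fetal_sex": "male"}
    center = (3500.0 + 60.0) * np.exp(0.01 * (246 - 280))
    curve = ZscoreCurveParams(
        ga_days=GA, median_g=(3500.0 + 60.0) * np.exp(0.01 * (GA - 280)), sigma=0.11
    )
    for w in (2100.0, center, 2900.0):
        p_cust, _ = epw_customized(w, 246, profile, params)
        p_z, _ = epw_zscore(w, 246, curve)
        assert float(p_cust) == pytest.approx(float(p_z), abs=1e-6)
    assert float(epw_customized(center, 246, profile, params)[0]) == pytest.approx(50.0, abs=1e-9)


def test_taller_mother_lowers_percentile():
    params = _cust_params()
    short = {"maternal_height_cm": 158.0, "fetal_sex": "female"}
    tall = {"maternal_height_cm": 175.0, "fetal_sex": "female"}
    p_short, _ = epw_customized(2500.0, 246, short, params)
    p_tall, _ = epw_customized(2500.0, 246, tall, params)
    assert float(p_tall) < float(p_short)


def test_doubled_expected_weight_lowers_percentile():
    small = _cust_params()
    big = CustomizationParams(
        base_term_weight=7000.0,
        reference_ga_days=280,
        prop_rate_per_day=0.01,
        covariate_effects=small.covariate_effects,
        sigma=0.11,
    )
    profile = {"maternal_height_cm": 163.0, "fetal_sex": "male"}
    assert float(epw_customized(2500.0, 246, profile, big)[0]) < float(
        epw_customized(2500.0, 246, profile, small)[0]
    )


def test_missing_covariate_named():
    with pytest.raises(MissingCovariateError, match="maternal_height_cm"):
        epw_customized(2500.0, 246, {"fetal_sex": "male"}, _cust_params())


# ---------------------------------------------------------------------------
# quantile grid


def test_grid_node_identities():
    grid = _grid()
    nodes = grid.weights_at(245.0)
    for level, w in zip(grid.levels, nodes):
        assert epw_quantile_grid(w, 245, grid) == pytest.approx(level, abs=1e-9)


def test_grid_probit_midpoint():
    """A weight halfway (probit scale is the construction here) between P25
    and P50 maps to Phi(midpoint of the probits of .25 and .50)."""
    grid = _grid()
    nodes = grid.weights_at(245.0)
    w_mid = 0.5 * (nodes[2] + nodes[3])
    frac = (w_mid - nodes[2]) / (nodes[3] - nodes[2])
    probit = norm.ppf(0.25) + frac * (norm.ppf(0.50) - norm.ppf(0.25))
    assert epw_quantile_grid(w_mid, 245, grid) == pytest.approx(100 * norm.cdf(probit), abs=0.1)


def test_grid_rejects_non_monotone_levels():
    grid = _grid()
    bad = grid.weights_g.copy()
    bad[0, 3] = bad[0, 2] - 1.0
    with pytest.raises(ParameterError):
        QuantileGrid(ga_days=grid.ga_days, weights_g=bad)


def test_family_equivalence_zscore_vs_grid(registry):
    """A quantile grid tabulated from a z-score standard reproduces that
    standard's percentiles within 0.5 points across the P5-P95 span."""
    spec = registry["msuh_nc"]
    levels = np.array([5, 10, 25, 50, 75, 90, 95], dtype=float)
    ga_nodes = np.array([238, 246, 252, 258])
    weights = np.array(
        [spec.weight_at_percentile(levels, float(g)) for g in ga_nodes]
    )
    grid = QuantileGrid(ga_days=ga_nodes, weights_g=weights)
    probe_p = np.linspace(6.0, 94.0, 45)
    for ga in (240, 246, 255):
        w = spec.weight_at_percentile(probe_p, ga)
        via_grid = epw_quantile_grid(w, ga, grid)
        assert np.max(np.abs(via_grid - probe_p)) < 0.5


# ---------------------------------------------------------------------------
# inverses and dispatch


@pytest.mark.parametrize("sid", ["msuh_nc", "msuh_cust", "figueras", "intergrowth21", "who", "fmf"])
def test_weight_percentile_round_trip(registry, sid):
    spec = registry[sid]
    profile = {
        "maternal_height_cm": 165.0,
        "paternal_height_cm": 178.0,
        "maternal_bmi": 24.0,
        "maternal_age_yr": 31.0,
        "parity": "1",
        "ethnicity": "Caucasian",
        "fetal_sex": "female",
    }
    for p in (5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0):
        w = spec.weight_at_percentile(p, 246, profile)
        back, _ = spec.percentile(float(w), 246, profile)
        assert float(back) == pytest.approx(p, abs=0.1)


def test_inverse_at_center_is_median(registry):
    spec = registry["msuh_nc"]
    med = spec.params.median_at(246)
    assert spec.weight_at_percentile(50.0, 246) == pytest.approx(float(med), rel=1e-9)


def test_inverse_rejects_out_of_range_percentile(registry):
    with pytest.raises(ValidationError):
        registry["msuh_nc"].weight_at_percentile(0.0, 246)


def test_full_record_yields_six_results(registry):
    rec = generate_cohort(CohortConfig(n_records=1, seed=9))[0]
    results = epw_all_standards(rec, registry)
    assert len(results) == 6
    assert all(r is not None for r in results.values())
    assert all(0.0 < r.percentile < 100.0 for r in results.values())


def test_missing_paternal_height_excludes_only_customized_msuh(registry):
    rec = generate_cohort(CohortConfig(n_records=1, seed=9))[0]
    rec.paternal_height_cm = None
    results = epw_all_standards(rec, registry)
    assert results["msuh_cust"] is None
    assert sum(r is not None for r in results.values()) == 5


def test_exclusion_counts_sum_to_cohort_size(registry, cohort):
    frame = cohort[0].copy().head(200)
    frame.loc[frame.index[:17], "fl_mm"] = np.nan
    frame.loc[frame.index[5:11], "paternal_height_cm"] = np.nan
    tally = exclusion_tally(epw_table(frame, registry))
    for sid, t in tally.items():
        assert t["analyzed"] + t["excluded"] == 200, sid
    assert tally["msuh_nc"]["excluded"] == 17
    assert tally["intergrowth21"]["excluded"] == 0


def test_chart_export_monotone(registry):
    from epwscreen.standards import chart_frame

    profile = {
        "maternal_height_cm": 165.0, "paternal_height_cm": 178.0, "maternal_bmi": 24.0,
        "maternal_age_yr": 31.0, "parity": "1", "ethnicity": "Caucasian", "fetal_sex": "female",
    }
    for sid, spec in registry.items():
        chart = chart_frame(spec, profile if spec.family == "customized" else None)
        assert list(chart["ga_days"]) == list(range(238, 259))
        cols = [c for c in chart.columns if c != "ga_days"]
        vals = chart[cols].to_numpy()
        assert np.all(np.diff(vals, axis=1) > 0), sid  # increasing across levels
        assert np.all(np.diff(vals, axis=0) >= 0), sid  # nondecreasing in GA


def test_standard_file_validation_errors():
    with pytest.raises(ParameterError, match="family"):
        standard_from_dict({"standard_id": "x", "efw_formula_id": "hadlock4", "parameters": {}})
    with pytest.raises(ParameterError):
        standard_from_dict(
            {
                "standard_id": "x",
                "family": "quantile_grid",
                "efw_formula_id": "hadlock4",
                "parameters": {
                    "ga_days": [238, 245],
                    "weights_g": [[7, 6, 5, 4, 3, 2, 1], [7, 6, 5, 4, 3, 2, 1]],
                },
            }
        )
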