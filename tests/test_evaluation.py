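"""Screening statistics against brute-force and simulation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm
from statsmodels.stats.proportion import proportions_ztest

from epwscreen.errors import AlignmentError, DegenerateClassesError, SeparationError, ValidationError
from epwscreen.evaluation import (
    INTERVAL_BUCKETS,
    auc_delong,
    delong_paired_test,
    logistic_or_per_percent,
    pairwise_comparisons,
    round_half_up,
    screen_eval,
    sensitivity_at_fpr,
    stratify_by_interval,
    two_proportion_test,
)

from oracles import brute_force_auc, brute_force_sens, grid_search_slope


# ---------------------------------------------------------------------------
# AUC


def test_auc_perfect_separation():
    scores = np.array([1.0, 2.0, 3.0, 80.0, 90.0, 95.0])
    labels = np.array([True, True, True, False, False, False])
    auc, lo, hi = auc_delong(scores, labels)
    assert auc == 1.0
    assert hi == 1.0  # CI clamped at the top


def test_auc_all_ties_is_half():
    auc, _, _ = auc_delong(np.full(10, 42.0), np.arange(10) < 4)
    assert auc == pytest.approx(0.5)


def test_auc_interleaved_matches_exhaustive_pair_count():
    scores = np.array([1, 3, 5, 7, 9, 11, 2, 4, 6, 8, 10, 12], dtype=float)
    labels = np.array([True] * 6 + [False] * 6)
    auc, _, _ = auc_delong(scores, labels)
    assert auc == pytest.approx(brute_force_auc(scores, labels))


def test_auc_matches_brute_force_on_small_instances(rng):
    """Midrank AUC equals exhaustive pair counting on random tied instances
    of every size up to 12."""
    for trial in range(300):
        n = int(rng.integers(2, 13))
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
        scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        assert auc_delong(scores, labels)[0] == pytest.approx(
            brute_force_auc(scores, labels)
        )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.data())
def test_auc_invariant_under_monotone_transform(data):
    n = data.draw(st.integers(6, 40))
    scores = np.array(data.draw(st.lists(st.integers(0, 30), min_size=n, max_size=n)), float)
    n_pos = data.draw(st.integers(1, n - 1))
    labels = np.zeros(n, dtype=bool)
    labels[:n_pos] = True
    a1 = auc_delong(scores, labels)[0]
    a2 = auc_delong(np.exp(scores / 10.0) * 3.0 + 1.0, labels)[0]
    assert a1 == pytest.approx(a2)


def test_auc_requires_both_classes():
    with pytest.raises(DegenerateClassesError):
        auc_delong([1.0, 2.0], [True, True])


def test_auc_ci_contains_point_estimate(cohort):
    frame, epw, outcomes = cohort
    auc, lo, hi = auc_delong(epw["pct_msuh_nc"], outcomes["sga"])
    assert lo <= auc <= hi
    assert 0.0 <= lo and hi <= 1.0


# ---------------------------------------------------------------------------
# DeLong paired test


def test_paired_test_self_comparison_is_one(cohort):
    frame, epw, outcomes = cohort
    p = delong_paired_test(epw["pct_msuh_nc"], epw["pct_msuh_nc"], outcomes["sga"])
    assert p == 1.0


def test_paired_test_alignment_error():
    with pytest.raises(AlignmentError):
        delong_paired_test([1.0, 2.0], [1.0], [True, False])


def test_paired_test_close_to_bootstrap_on_small_instance(rng):
    """On n=20 the DeLong p is within 0.02 of a stratified-bootstrap
    (B=20000) normal-approximation p for the AUC difference."""
    n = 20
    latent = rng.normal(size=n)
    labels = latent < norm.ppf(0.4)
    a = latent + rng.normal(0, 0.6, n)
    b = latent + rng.normal(0, 0.6, n)
    p_delong = delong_paired_test(a, b, labels)

    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    B = 20000
    diffs = np.empty(B)
    for i in range(B):
        idx = np.concatenate(
            [rng.choice(pos_idx, pos_idx.size), rng.choice(neg_idx, neg_idx.size)]
        )
        lab = np.concatenate([np.ones(pos_idx.size, bool), np.zeros(neg_idx.size, bool)])
        diffs[i] = auc_delong(a[idx], lab)[0] - auc_delong(b[idx], lab)[0]
    d0 = auc_delong(a, labels)[0] - auc_delong(b, labels)[0]
    p_boot = 2 * norm.sf(abs(d0) / diffs.std(ddof=1))
    assert abs(p_delong - p_boot) < 0.02


# ---------------------------------------------------------------------------
# sensitivity at fixed FPR


def test_sensitivity_separated_case():
    scores = np.array([1.0, 2.0, 50.0, 60.0, 70.0, 80.0])
    labels = np.array([True, True, False, False, False, False])
    sens, ci, thr, ach = sensitivity_at_fpr(scores, labels, 5.0)
    assert sens == 100.0
    assert ach <= 5.0


def test_sensitivity_spec_example_scan():
    scores = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 5, 15, 25, 35, 45], float)
    labels = np.array([False] * 10 + [True] * 5)
    sens, _, thr, ach = sensitivity_at_fpr(scores, labels, 20.0)
    bf_sens, bf_thr = brute_force_sens(scores, labels, 20.0)
    assert sens == pytest.approx(bf_sens)
    assert thr == pytest.approx(bf_thr)


def test_sensitivity_matches_brute_force_scan(rng):
    """200 random tied instances: threshold and sensitivity equal an
    exhaustive scan over all candidate thresholds."""
    for _ in range(200):
        n = int(rng.integers(8, 60))
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
        scores = rng.choice(np.linspace(1, 99, 25), size=n)
        target = float(rng.choice([5.0, 10.0, 15.0, 20.0, 50.0]))
        sens, _, thr, ach = sensitivity_at_fpr(scores, labels, target)
        bf_sens, bf_thr = brute_force_sens(scores, labels, target)
        assert sens == pytest.approx(bf_sens)
        assert thr == pytest.approx(bf_thr)
        assert ach <= target + 1e-9


def test_sensitivity_at_full_fpr_is_total():
    scores = np.array([10.0, 50.0, 70.0, 99.99])
    labels = np.array([True, False, True, False])
    sens, _, _, _ = sensitivity_at_fpr(scores, labels, 100.0)
    assert sens == 100.0


def test_sensitivity_monotone_in_target(cohort):
    frame, epw, outcomes = cohort
    ev = screen_eval(epw["pct_fmf"], outcomes["sga"])
    sens = [e.sensitivity for e in ev.by_fpr]
    thr = [e.threshold_percentile for e in ev.by_fpr]
    assert sens == sorted(sens)
    assert thr == sorted(thr)
    assert all(e.achieved_fpr <= e.target_fpr + 1e-9 for e in ev.by_fpr)


# ---------------------------------------------------------------------------
# proportion test


def test_two_proportion_strong_difference():
    assert two_proportion_test(174, 645, 51, 645) < 0.001


def test_two_proportion_identical_is_one():
    assert two_proportion_test(10, 100, 10, 100) == 1.0


def test_two_proportion_matches_hand_formula_and_statsmodels():
    k1, n1, k2, n2 = 3, 10, 7, 10
    pool = (k1 + k2) / (n1 + n2)
    z = (k1 / n1 - k2 / n2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    expected = 2 * norm.sf(abs(z))
    assert two_proportion_test(k1, n1, k2, n2) == pytest.approx(expected, abs=1e-6)
    stat, p_sm = proportions_ztest([k1, k2], [n1, n2])
    assert two_proportion_test(k1, n1, k2, n2) == pytest.approx(p_sm, abs=1e-12)


def test_two_proportion_invalid_counts():
    with pytest.raises(ValidationError):
        two_proportion_test(5, 3, 1, 10)


# ---------------------------------------------------------------------------
# logistic OR


def test_logistic_slope_matches_grid_search(rng):
    x = rng.uniform(1, 99, size=30)
    y = (rng.uniform(size=30) < 1.0 / (1.0 + np.exp(0.05 * (x - 40)))).astype(float)
    if y.sum() in (0, 30):
        y[0], y[-1] = 1.0, 0.0
    orr, lo, hi = logistic_or_per_percent(x, y > 0.5)
    assert np.log(orr) == pytest.approx(grid_search_slope(x, y), abs=1e-4)


def test_logistic_null_ci_contains_one(rng):
    x = rng.uniform(0, 100, 600)
    y = rng.uniform(size=600) < 0.3
    orr, lo, hi = logistic_or_per_percent(x, y)
    assert lo < 1.0 < hi


def test_logistic_or_below_one_when_high_percentile_protective(cohort):
    frame, epw, outcomes = cohort
    orr, lo, hi = logistic_or_per_percent(epw["pct_msuh_nc"], outcomes["sga"])
    assert hi < 1.0


def test_logistic_complete_separation_raises():
    x = np.array([1.0, 2.0, 3.0, 50.0, 60.0, 70.0])
    y = np.array([True, True, True, False, False, False])
    with pytest.raises(SeparationError):
        logistic_or_per_percent(x, y)


# ---------------------------------------------------------------------------
# interval strata & pairwise matrix


def test_interval_bucket_edges(cohort):
    frame, epw, outcomes = cohort
    assert INTERVAL_BUCKETS[1] == (8, 14)
    assert INTERVAL_BUCKETS[2] == (15, 21)
    f = frame.copy()
    interval = f["ga_delivery_days"] - f["ga_scan_days"]
    strata = stratify_by_interval(f, epw, outcomes["sga"], ["msuh_nc"])
    in_range = ((interval >= 8) & (interval <= 49)).sum()
    assert sum(s.n for s in strata) == in_range
    # explicit edge assignments
    assert ((interval == 14)).sum() == ((interval == 14) & (interval >= 8) & (interval <= 14)).sum()


def test_interval_stratum_membership_at_edges(registry, reference):
    from epwscreen.outcomes import outcome_frame
    from epwscreen.standards import epw_table
    from epwscreen.synthetic_cohort import CohortConfig, generate_frame

    frame = generate_frame(CohortConfig(n_records=400, seed=55))
    frame["ga_scan_days"] = 252
    frame.loc[frame.index[:100], "ga_delivery_days"] = 252 + 14
    frame.loc[frame.index[100:200], "ga_delivery_days"] = 252 + 15
    frame.loc[frame.index[200:300], "ga_delivery_days"] = 252 + 7  # excluded
    frame.loc[frame.index[300:], "ga_delivery_days"] = 252 + 30
    epw = epw_table(frame, registry)
    out = outcome_frame(frame, reference)
    strata = stratify_by_interval(frame, epw, out["sga"], ["msuh_nc"])
    by_label = {s.label: s.n for s in strata}
    assert by_label[1] == 100 and by_label[2] == 100 and by_label[4] == 100
    assert sum(by_label.values()) == 300  # the 7-day records are excluded


def test_degenerate_stratum_reported_not_raised(registry, reference):
    from epwscreen.outcomes import outcome_frame
    from epwscreen.standards import epw_table
    from epwscreen.synthetic_cohort import CohortConfig, generate_frame

    frame = generate_frame(CohortConfig(n_records=50, seed=56))
    frame["ga_scan_days"] = 252
    frame["ga_delivery_days"] = 252 + 10
    frame["birthweight_g"] = 4000.0  # nobody is SGA
    epw = epw_table(frame, registry)
    out = outcome_frame(frame, reference)
    strata = stratify_by_interval(frame, epw, out["sga"], ["msuh_nc"])
    s1 = [s for s in strata if s.label == 1][0]
    assert s1.not_evaluable_reason is not None


def test_pairwise_matrix_symmetry(cohort):
    frame, epw, outcomes = cohort
    ids = ["msuh_nc", "fmf", "who"]
    pairs = pairwise_comparisons(epw, outcomes["sga"], outcomes["any_apo"], ids)
    assert len(pairs) == 3
    for p in pairs:
        assert 0.0 <= p.auc_p <= 1.0
        assert 0.0 <= p.sens_p <= 1.0
        assert 0.0 <= p.apo_p <= 1.0
    # self-comparison p = 1 on the diagonal by convention
    assert delong_paired_test(epw["pct_fmf"], epw["pct_fmf"], outcomes["sga"]) == 1.0


def test_round_half_up():
    assert round_half_up(21.55, 1) == 21.6
    assert round_half_up(2.6499, 1) == 2.6
    assert round_half_up(8.1794, 1) == 8.2
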