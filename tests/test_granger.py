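"""Granger causality: pairwise F test, conditional VAR, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restconn import (
    ROITimeSeriesSet,
    aggregate_group,
    build_var_model,
    check_stationarity,
    conditional_granger,
    pairwise_granger,
    segment_windows,
    simulate_cohort,
    window_influences,
)
from restconn.granger import WindowGC


class TestSegmentWindows:
    def test_sixty_second_windows_at_tr_two(self):
        x = np.zeros((190, 2))
        windows = segment_windows(x, 60.0, 2.0)
        assert len(windows) == 6
        assert all(w.shape == (30, 2) for w in windows)

    def test_exact_division_drops_nothing(self):
        windows = segment_windows(np.zeros((60, 1)), 60.0, 2.0)
        assert len(windows) == 2

    def test_fifty_second_window_allowed(self):
        windows = segment_windows(np.zeros((100, 1)), 50.0, 2.0)
        assert len(windows) == 4 and windows[0].shape[0] == 25

    def test_non_integral_window_rejected(self):
        with pytest.raises(ValueError, match="integral"):
            segment_windows(np.zeros((100, 1)), 45.0, 2.0)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            segment_windows(np.zeros((100, 1)), 20.0, 2.0)


class TestPairwiseGranger:
    def test_strong_lagged_coupling_detected(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(101)
        y = np.empty(101)
        y[0] = 0.0
        y[1:] = 0.9 * x[:-1]
        y += 0.05 * rng.standard_normal(101)
        res = pairwise_granger(x, y, m=1)
        assert res.p < 1e-6
        assert res.influence > 1.0

    def test_shifted_copy_handled_without_overflow(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(80)
        y = np.roll(x, 1)
        res = pairwise_granger(x[1:], y[1:], m=1)
        assert np.isfinite(res.F) or res.F == np.inf
        assert res.influence > 5 or res.influence == np.inf
        assert res.p < 1e-10

    def test_degrees_of_freedom_guard(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            pairwise_granger(np.arange(6.0), np.arange(6.0) ** 2, m=2)

    def test_constant_series_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            pairwise_granger(np.ones(30), np.random.default_rng(0).normal(size=30))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_nesting_invariant(self, seed):
        rng = np.random.default_rng(seed)
        t_len = int(rng.integers(12, 60))
        m = int(rng.integers(1, 3))
        if t_len - m - 2 * m - 1 <= 0:
            t_len = 3 * m + 4 + m
        x = rng.standard_normal(t_len)
        y = rng.standard_normal(t_len)
        res = pairwise_granger(x, y, m=m)
        assert res.rss_unrestricted <= res.rss_restricted + 1e-12
        assert res.F >= 0 and res.influence >= 0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_affine_rescaling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50) + 0.4 * np.roll(x, 1)
        base = pairwise_granger(x, y, m=1)
        scaled = pairwise_granger(3.5 * x - 2.0, 0.2 * y + 7.0, m=1)
        assert scaled.F == pytest.approx(base.F, rel=1e-8)
        assert scaled.influence == pytest.approx(base.influence, rel=1e-8)

    def test_matches_statsmodels_reference(self):
        from statsmodels.tsa.stattools import grangercausalitytests

        rng = np.random.default_rng(5)
        x = rng.standard_normal(600)
        y = np.empty(600)
        y[0] = rng.standard_normal()
        for t in range(1, 600):
            y[t] = 0.3 * y[t - 1] + 0.4 * x[t - 1] + rng.standard_normal()
        res = pairwise_granger(x, y, m=1)
        sm = grangercausalitytests(
            np.column_stack([y, x]), maxlag=1, verbose=False
        )[1][0]["ssr_ftest"]
        # same df convention; only difference is intercept vs demeaning
        assert res.F == pytest.approx(sm[0], rel=0.02)
        assert res.p == pytest.approx(sm[1], abs=1e-6)


class TestConditionalGranger:
    def test_chain_graph_contrast(self):
        # x -> y -> z with no direct x -> z: conditional GC should clear
        # x -> z while pairwise GC (which cannot control for y) flags it.
        rng = np.random.default_rng(2)
        n = 500
        x = np.empty(n)
        y = np.empty(n)
        z = np.empty(n)
        x[0] = y[0] = z[0] = 0.0
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + rng.standard_normal()
            y[t] = 0.8 * x[t - 1] + 0.2 * y[t - 1] + 0.3 * rng.standard_normal()
            z[t] = 0.8 * y[t - 1] + 0.2 * z[t - 1] + 0.3 * rng.standard_normal()
        seg = np.column_stack([x, y, z])
        cond = conditional_granger(seg, m=1, roi_labels=("x", "y", "z"))
        pair = pairwise_granger(x, z, m=1)
        assert pair.p < 1e-6
        assert cond.p[0, 2] > 0.01
        assert cond.influence[0, 2] < 0.05
        assert cond.p[0, 1] < 1e-10 and cond.p[1, 2] < 1e-10

    def test_independent_system_has_near_zero_influence(self):
        rng = np.random.default_rng(3)
        seg = rng.standard_normal((400, 4))
        res = conditional_granger(seg, m=1)
        off = ~np.eye(4, dtype=bool)
        assert np.all(res.influence[off] < 0.05)

    def test_reduces_to_pairwise_for_two_rois(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(60)
        y = rng.standard_normal(60) + 0.5 * np.roll(x, 1)
        seg = np.column_stack([x, y])
        cond = conditional_granger(seg, m=1)
        pair = pairwise_granger(x, y, m=1)
        assert cond.F[0, 1] == pytest.approx(pair.F, rel=1e-9)
        assert cond.influence[0, 1] == pytest.approx(pair.influence, rel=1e-9)

    def test_insufficient_observations_rejected(self):
        seg = np.random.default_rng(0).standard_normal((22, 18))
        with pytest.raises(ValueError, match="pairwise"):
            conditional_granger(seg, m=1)


class TestStationarity:
    def test_white_noise_passes_screen(self):
        rng = np.random.default_rng(6)
        passes = sum(
            check_stationarity(rng.standard_normal((30, 1))).passes
            for _ in range(300)
        )
        assert passes >= 0.93 * 300

    def test_random_walk_fails_screen(self):
        rng = np.random.default_rng(7)
        fails = sum(
            not check_stationarity(
                np.cumsum(rng.standard_normal((200, 1)), axis=0)
            ).passes
            for _ in range(100)
        )
        assert fails >= 85

    def test_detrended_trend_series_passes(self):
        from restconn import detrend_and_demean

        rng = np.random.default_rng(8)
        mat = np.arange(60.0)[:, None] * 0.5 + rng.standard_normal((60, 1))
        ts = ROITimeSeriesSet([mat], ["a"], 2.0)
        out = detrend_and_demean(ts)
        assert check_stationarity(out.data[0]).passes

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            check_stationarity(np.random.default_rng(0).normal(size=(10, 1)))


def _planted_cohort(n_subjects=12, n_timepoints=180, seed=100):
    """3-ROI cohort with a single planted x -> y link."""
    from restconn import CausalGraphSpec

    coeff = np.zeros((1, 3, 3))
    coeff[0, 1, 0] = 0.6  # x -> y
    np.fill_diagonal(coeff[0], 0.2)
    spec = CausalGraphSpec(("x", "y", "z"), 1, coeff, np.eye(3), seed=seed)
    return simulate_cohort(
        build_var_model(spec), n_subjects, n_timepoints, seed=seed
    )


class TestAggregateGroup:
    def test_planted_edge_recovered_with_direction(self):
        cohort = _planted_cohort()
        results, _ = window_influences(cohort, 60.0, 1, "conditional")
        group = aggregate_group(results, cohort.roi_labels, 0.001)
        pairs = group.edges.pairs()
        assert ("x", "y") in pairs
        assert ("y", "x") not in pairs
        # every significant edge carries positive mean influence
        assert all(e.weight > 0 for e in group.edges)

    def test_subject_t_method_also_recovers_strong_edge(self):
        cohort = _planted_cohort()
        results, _ = window_influences(cohort, 60.0, 1, "conditional")
        group = aggregate_group(
            results, cohort.roi_labels, 0.001, method="subject-t"
        )
        assert ("x", "y") in group.edges.pairs()

    def test_pairwise_mode_recovers_planted_edge(self):
        cohort = _planted_cohort()
        results, _ = window_influences(cohort, 60.0, 1, "pairwise")
        group = aggregate_group(results, cohort.roi_labels, 0.001)
        assert ("x", "y") in group.edges.pairs()

    def test_single_subject_aborts(self):
        cohort = _planted_cohort(n_subjects=1)
        results, _ = window_influences(cohort, 60.0, 1, "conditional")
        with pytest.raises(ValueError, match=">= 3 subjects"):
            aggregate_group(results, cohort.roi_labels, 0.001)

    def test_subject_without_windows_excluded_with_warning(self):
        cohort = _planted_cohort(n_subjects=4)
        results, _ = window_influences(cohort, 60.0, 1, "conditional")
        results[0] = []
        with pytest.warns(UserWarning, match="no valid windows"):
            group = aggregate_group(results, cohort.roi_labels, 0.001)
        assert group.n_subjects == 3

    def test_familywise_error_on_null_cohorts(self, null_spec_4):
        model = build_var_model(null_spec_4)
        n_rep = 150
        any_edge = 0
        for k in range(n_rep):
            cohort = simulate_cohort(model, 10, 90, seed=70_000 + k)
            results, _ = window_influences(cohort, 60.0, 1, "conditional")
            group = aggregate_group(results, cohort.roi_labels, 0.001)
            any_edge += len(group.edges) > 0
        # nominal familywise error .001 -> essentially no rejections
        assert any_edge <= 2


class TestWindowInfluences:
    def test_diagnostics_report_window_accounting(self):
        cohort = _planted_cohort(n_subjects=3, n_timepoints=190)
        results, diag = window_influences(cohort, 60.0, 1, "conditional")
        assert diag["windows_used"] == 18  # 3 subjects x 6 windows
        assert all(len(r) == 6 for r in results)
        assert isinstance(results[0][0], WindowGC)

    def test_strict_policy_may_exclude_windows(self):
        cohort = _planted_cohort(n_subjects=3)
        _, diag = window_influences(
            cohort, 60.0, 1, "conditional", stationarity="strict"
        )
        assert diag["windows_excluded"] == diag["windows_flagged_stationarity"]

    def test_unknown_mode_rejected(self):
        cohort = _planted_cohort(n_subjects=3)
        with pytest.raises(ValueError, match="mode"):
            window_influences(cohort, 60.0, 1, "spectral")
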