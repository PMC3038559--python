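"""Synthetic VAR cohort generator: validity, determinism, ground truth."""

import numpy as np
import pytest
from scipy import linalg

from restconn import (
    CausalGraphSpec,
    build_var_model,
    correlation_truth,
    directed_edge_mask,
    pearson_matrix,
    simulate_cohort,
    spectral_radius,
    stationary_covariance,
)
from restconn.cohort import sensory_roi_labels


class TestSpecValidation:
    def test_unstable_coefficients_rejected_with_radius(self):
        coeff = np.array([[[1.05]]])
        with pytest.raises(ValueError, match=r"radius 1\.05"):
            CausalGraphSpec(("x",), 1, coeff, np.eye(1))

    def test_non_positive_definite_noise_rejected_with_eigenvalue(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="eigenvalue"):
            CausalGraphSpec(("x", "y"), 1, np.zeros((1, 2, 2)), bad)

    def test_asymmetric_noise_rejected(self):
        bad = np.array([[1.0, 0.2], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            CausalGraphSpec(("x", "y"), 1, np.zeros((1, 2, 2)), bad)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CausalGraphSpec(("x", "x"), 1, np.zeros((1, 2, 2)), np.eye(2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="coeff shape"):
            CausalGraphSpec(("x", "y"), 1, np.zeros((1, 3, 3)), np.eye(2))


class TestSampler:
    def test_zero_coefficients_give_white_noise(self):
        spec = CausalGraphSpec(("x", "y"), 1, np.zeros((1, 2, 2)), np.eye(2), seed=1)
        x = build_var_model(spec).simulate(4000, rng=1)
        for j in range(2):
            col = x[:, j] - x[:, j].mean()
            rho1 = np.dot(col[1:], col[:-1]) / np.dot(col, col)
            assert abs(rho1) < 3 / np.sqrt(len(col))
        assert abs(x.var() - 1.0) < 0.1

    def test_lyapunov_oracle_matches_simulation(self, two_roi_spec):
        # independent oracle: companion-form discrete Lyapunov solution
        a = two_roi_spec.coeff[0]
        sigma = linalg.solve_discrete_lyapunov(a, np.eye(2))
        assert np.allclose(stationary_covariance(two_roi_spec), sigma)
        x = build_var_model(two_roi_spec).simulate(50_000, rng=0)
        emp = np.cov(x, rowvar=False)
        assert np.all(np.abs(emp - sigma) / np.abs(sigma) < 0.05)
        # lag-1 cross-covariance: Gamma_1 = A Sigma
        xc = x - x.mean(axis=0)
        emp_lag1 = xc[1:].T @ xc[:-1] / (len(x) - 1)
        assert np.all(np.abs(emp_lag1 - a @ sigma) < 0.05)

    def test_sampler_deterministic_given_seed(self, two_roi_spec):
        model = build_var_model(two_roi_spec)
        assert np.array_equal(model.simulate(100, rng=5), model.simulate(100, rng=5))


class TestSimulateCohort:
    def test_cohort_dimensions_match_study_conditions(self, pattern_cohort):
        assert pattern_cohort.n_subjects == 29
        assert pattern_cohort.n_rois == 18
        assert all(mat.shape == (200, 18) for mat in pattern_cohort.data)
        assert pattern_cohort.tr_seconds == 2.0

    def test_cohort_reproducible_bit_for_bit(self, two_roi_spec):
        model = build_var_model(two_roi_spec)
        c1 = simulate_cohort(model, 4, 60, seed=9)
        c2 = simulate_cohort(model, 4, 60, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(c1.data, c2.data))

    def test_jitter_bounds_validated(self, two_roi_spec):
        model = build_var_model(two_roi_spec)
        with pytest.raises(ValueError, match="subject_jitter"):
            simulate_cohort(model, 2, 60, subject_jitter=1.5, seed=0)

    def test_short_series_rejected(self, two_roi_spec):
        model = build_var_model(two_roi_spec)
        with pytest.raises(ValueError, match="too short"):
            simulate_cohort(model, 2, 5, seed=0)

    def test_null_cohort_pearson_mean_near_zero(self, null_spec_4):
        model = build_var_model(null_spec_4)
        cohort = simulate_cohort(model, 29, 190, seed=21)
        rs = np.array(
            [pearson_matrix(mat).r[0, 1] for _, mat in cohort]
        )
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean()) < 3 * se + 1e-12 or abs(rs.mean()) < 3 / np.sqrt(29 * 188)


class TestSensoryPatternGraph:
    def test_spec_is_stationary_and_positive_definite(self, pattern_spec):
        assert spectral_radius(pattern_spec.coeff) < 1
        assert np.linalg.eigvalsh(pattern_spec.noise_cov)[0] > 0

    def test_directed_skeleton_matches_information_flow(self, pattern_spec):
        labels = pattern_spec.roi_labels
        mask = directed_edge_mask(pattern_spec)
        idx = {lab: i for i, lab in enumerate(labels)}
        # frontal cortex receives from olfactory and motor, not the reverse
        for h in ("L", "R"):
            assert mask[idx[f"olfactory_{h}"], idx[f"prefrontal_{h}"]]
            assert mask[idx[f"motor_{h}"], idx[f"prefrontal_{h}"]]
            assert not mask[idx[f"prefrontal_{h}"], idx[f"olfactory_{h}"]]
            # amygdala communicates bidirectionally with the sensory cortices
            for region in ("olfactory", "auditory", "somatosensory", "visual", "motor"):
                assert mask[idx[f"amygdala_{h}"], idx[f"{region}_{h}"]]
                assert mask[idx[f"{region}_{h}"], idx[f"amygdala_{h}"]]

    def test_olfactory_visual_innovation_coupling_negative(self, pattern_spec):
        idx = {lab: i for i, lab in enumerate(pattern_spec.roi_labels)}
        assert pattern_spec.noise_cov[idx["olfactory_L"], idx["visual_L"]] < 0

    def test_correlation_truth_is_polarised(self, pattern_spec):
        rho, planted, null = correlation_truth(pattern_spec)
        iu = np.triu_indices(18, k=1)
        n_planted = planted[iu].sum()
        n_null = null[iu].sum()
        assert n_planted >= 30 and n_null >= 30
        assert np.abs(rho[iu])[planted[iu]].min() >= 0.33
        assert np.abs(rho[iu])[null[iu]].max() <= 0.03

    def test_planted_correlations_never_contradict_listed_signs(self, pattern_spec):
        from restconn.cohort import CORRELATION_SIGNS

        rho, planted, _ = correlation_truth(pattern_spec)
        labels = pattern_spec.roi_labels
        iu = np.triu_indices(18, k=1)
        for k, (i, j) in enumerate(zip(*iu)):
            if not planted[i, j]:
                continue
            region_a = labels[i].rsplit("_", 1)[0]
            region_b = labels[j].rsplit("_", 1)[0]
            listed = CORRELATION_SIGNS.get(frozenset((region_a, region_b)))
            if listed is not None:
                assert np.sign(rho[i, j]) == listed
        # innovation couplings on listed pairs never carry the wrong sign
        idx = {lab: i for i, lab in enumerate(labels)}
        for pair, s in CORRELATION_SIGNS.items():
            ra, rb = sorted(pair)
            for h in ("L", "R"):
                q = pattern_spec.noise_cov[idx[f"{ra}_{h}"], idx[f"{rb}_{h}"]]
                assert np.sign(q) != -s

    def test_labels_cover_both_hemispheres_of_nine_regions(self):
        labels = sensory_roi_labels()
        assert len(labels) == 18
        assert sum(lab.endswith("_L") for lab in labels) == 9
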