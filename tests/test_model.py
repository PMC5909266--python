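"""Quadratic position+velocity model and phase-linear comparator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import respsurro as rs
from respsurro.core import DegenerateBranchError, DegenerateFitError, InvalidInputError
from respsurro.model import design_matrix, predict_phase_linear

from conftest import two_tone_surrogate


class TestFeatureVector:
    def test_zero_case(self):
        assert np.allclose(rs.feature_vector(0.0, 0.0, 0.2), [0, 0, 1, 0, 0])

    def test_hand_example(self):
        assert np.allclose(rs.feature_vector(2.0, 1.0, 0.2), [4, 2, 1, 25, 5])

    @settings(deadline=None, max_examples=100)
    @given(
        w=st.floats(-50, 50),
        w_prev=st.floats(-50, 50),
        delta=st.floats(-20, 20),
    )
    def test_velocity_shift_invariance(self, w, w_prev, delta):
        base = rs.feature_vector(w, w_prev, 0.2)
        shifted = rs.feature_vector(w + delta, w_prev + delta, 0.2)
        assert np.allclose(shifted[3:], base[3:], rtol=1e-9, atol=1e-7)


class TestQuadraticFit:
    def test_identity_mapping(self):
        """Target equal to the surrogate AP channel -> pure b=1 coefficient."""
        w = two_tone_surrogate()
        surr = tuple(rs.SurrogateTrace(m, w, 0.2) for m in (1, 2, 3))
        target = rs.TargetTrace(np.column_stack([w, w, w]), 0.2)
        scan = rs.Scan("ident", surr, target)
        coeffs = rs.fit_quadratic(scan, 1, rs.Direction.AP, 10.0)
        assert np.allclose(coeffs, [0, 1, 0, 0, 0], atol=1e-6)

    @pytest.mark.parametrize("t_m", [5.0, 10.0, 15.0, 25.0, 35.0])
    def test_generative_recovery(self, two_tone_scan, known_truth, t_m):
        model = rs.fit_quadratic_model(two_tone_scan, t_m)
        rel = np.abs(model.coeffs - known_truth.coeffs) / np.abs(known_truth.coeffs)
        assert rel.max() < 1e-6

    def test_matches_normal_equations_oracle(self, two_tone_scan):
        """Independent solve of X'X c = X'y on the same window."""
        from respsurro.core import split_sessions, tail_window

        split = split_sessions(two_tone_scan)
        idx = tail_window(split, 10.0, 0.2)
        idx = idx[idx >= 1]
        X = design_matrix(two_tone_scan.surrogate(2).positions, 0.2, idx)
        y = two_tone_scan.target.component(rs.Direction.SI)[idx]
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        ours = rs.fit_quadratic(two_tone_scan, 2, rs.Direction.SI, 10.0)
        assert np.allclose(ours, oracle, rtol=1e-8)

    def test_constant_surrogate_degenerate(self):
        w = np.full(351, 5.0)
        surr = tuple(rs.SurrogateTrace(m, w, 0.2) for m in (1, 2, 3))
        target = rs.TargetTrace(np.random.default_rng(0).normal(size=(351, 3)), 0.2)
        scan = rs.Scan("flat", surr, target)
        with pytest.raises(DegenerateFitError):
            rs.fit_quadratic(scan, 1, rs.Direction.SI, 10.0)

    def test_full_scan_training_period(self, two_tone_scan, known_truth):
        """T_M spanning the whole 70-s scan still recovers the truth."""
        model = rs.fit_quadratic_model(two_tone_scan, 70.0)
        assert np.allclose(model.coeffs, known_truth.coeffs, rtol=1e-6)


class TestPredictQuadratic:
    def test_constant_model(self):
        coeffs = np.zeros((3, 3, 5))
        coeffs[:, :, 2] = 4.2
        model = rs.QuadraticModel(coeffs, t_m=10.0)
        w = two_tone_surrogate(n=50)
        surr = tuple(rs.SurrogateTrace(m, w, 0.2) for m in (1, 2, 3))
        est = rs.predict_quadratic(model, surr, np.arange(1, 50))
        assert np.allclose(est, 4.2)

    def test_fit_then_predict_residuals_vanish(self, two_tone_scan):
        from respsurro.core import split_sessions, tail_window

        model = rs.fit_quadratic_model(two_tone_scan, 10.0)
        split = split_sessions(two_tone_scan)
        idx = tail_window(split, 10.0, 0.2)
        idx = idx[idx >= 1]
        est = rs.average_over_markers(
            rs.predict_quadratic(model, two_tone_scan.surrogates, idx)
        )
        assert np.max(np.abs(est - two_tone_scan.target.positions[idx])) < 1e-9

    def test_matches_feature_dot_product(self, two_tone_scan):
        model = rs.fit_quadratic_model(two_tone_scan, 15.0)
        rng = np.random.default_rng(4)
        idx = rng.integers(1, 351, size=10)
        est = rs.predict_quadratic(model, two_tone_scan.surrogates, idx)
        for i, marker in enumerate((1, 2, 3)):
            w = two_tone_scan.surrogate(marker).positions
            for j, k in enumerate(idx):
                W = rs.feature_vector(w[k], w[k - 1], 0.2)
                for g, d in enumerate(rs.DIRECTIONS):
                    assert est[i, j, g] == pytest.approx(
                        float(model.coefficients(marker, d) @ W), rel=1e-12
                    )

    def test_index_zero_rejected(self, two_tone_scan):
        model = rs.fit_quadratic_model(two_tone_scan, 10.0)
        with pytest.raises(InvalidInputError):
            rs.predict_quadratic(model, two_tone_scan.surrogates, np.array([0, 1]))


class TestMarkerAveraging:
    def test_mean_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        est = rng.normal(size=(3, 20, 3))
        avg = rs.average_over_markers(est)
        assert np.allclose(avg, est.mean(axis=0))
        assert np.allclose(avg, rs.average_over_markers(est[[2, 0, 1]]))

    def test_hand_values(self):
        est = np.array([[[1.0] * 3], [[2.0] * 3], [[3.0] * 3]])
        assert np.allclose(rs.average_over_markers(est), 2.0)


class TestPhaseLinear:
    w_ave = np.array([2.0, 4.0, 6.5, 8.0, 9.0, 7.5, 5.0, 3.0])

    def _linear_model(self, slope=2.0, intercept=1.0):
        p = slope * self.w_ave[:, None] + intercept * np.ones((8, 3))
        return rs.fit_phase_linear(self.w_ave, p)

    def test_exact_linear_relation(self):
        model = self._linear_model()
        assert np.allclose(model.slopes, 2.0, atol=1e-9)
        assert np.allclose(model.intercepts, 1.0, atol=1e-9)

    def test_centroid_of_ramp(self):
        p = np.arange(8.0)[:, None] * np.ones((8, 3))
        model = rs.fit_phase_linear(self.w_ave, p)
        assert np.allclose(model.centroid, 3.5)

    def test_slopes_match_two_point_oracle(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(8, 3))
        model = rs.fit_phase_linear(self.w_ave, p)
        for alpha in range(8):
            beta = (alpha + 1) % 8
            dw = self.w_ave[beta] - self.w_ave[alpha]
            assert np.allclose(model.slopes[alpha], (p[beta] - p[alpha]) / dw)
            assert np.allclose(
                model.intercepts[alpha], p[alpha] - model.slopes[alpha] * self.w_ave[alpha]
            )

    def test_degenerate_branch(self):
        w = self.w_ave.copy()
        w[1] = w[0]
        with pytest.raises(DegenerateBranchError):
            rs.fit_phase_linear(w, np.zeros((8, 3)))

    def test_knot_interpolation(self):
        rng = np.random.default_rng(2)
        p = rng.normal(size=(8, 3))
        model = rs.fit_phase_linear(self.w_ave, p)
        out = predict_phase_linear(model, self.w_ave[2], -1.0)
        assert np.allclose(out[0], p[2], atol=1e-12)

    def test_linear_coupling_branch_independent(self):
        model = self._linear_model(slope=-1.5, intercept=0.3)
        rng = np.random.default_rng(3)
        w = rng.uniform(0.0, 12.0, size=40)  # includes out-of-range values
        v = rng.normal(size=40)
        out = predict_phase_linear(model, w, v)
        assert np.allclose(out, -1.5 * w[:, None] + 0.3, atol=1e-9)

    def test_matches_exhaustive_branch_oracle(self):
        """Brute-force scan over the limb's branches with the same
        membership/clamp rule must agree at random query points."""
        rng = np.random.default_rng(5)
        p = rng.normal(size=(8, 3)) * 3.0
        model = rs.fit_phase_linear(self.w_ave, p)
        inhal, exhal = (0, 1, 2, 3), (4, 5, 6, 7)
        for _ in range(100):
            w = rng.uniform(1.0, 10.0)
            v = rng.normal()
            limb = exhal if v >= 0 else inhal
            best, best_dist = None, np.inf
            for alpha in limb:
                beta = (alpha + 1) % 8
                lo = min(self.w_ave[alpha], self.w_ave[beta])
                hi = max(self.w_ave[alpha], self.w_ave[beta])
                dist = max(lo - w, w - hi, 0.0)
                if dist == 0.0:
                    best = alpha
                    break
                if dist < best_dist:
                    best, best_dist = alpha, dist
            expected = model.slopes[best] * w + model.intercepts[best]
            assert np.allclose(predict_phase_linear(model, w, v)[0], expected)

    def test_continuity_within_limb(self):
        rng = np.random.default_rng(6)
        p = rng.normal(size=(8, 3))
        model = rs.fit_phase_linear(self.w_ave, p)
        ws = np.linspace(2.0, 9.0, 400)
        out = predict_phase_linear(model, ws, np.full_like(ws, -1.0))
        jumps = np.abs(np.diff(out, axis=0)).max()
        assert jumps < 0.2  # piecewise-linear through shared knots: no breaks

    def test_invert_breathing_sign_swaps_limbs(self):
        rng = np.random.default_rng(7)
        p = rng.normal(size=(8, 3))
        model = rs.fit_phase_linear(self.w_ave, p)
        w, v = 5.5, 1.0
        normal = predict_phase_linear(model, w, v)
        flipped = predict_phase_linear(model, w, -v)
        inverted = predict_phase_linear(model, w, v, invert_breathing_sign=True)
        assert np.allclose(inverted, flipped)
        assert not np.allclose(normal, flipped)
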