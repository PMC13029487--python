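"""Kalman update, unwrapping, Savitzky-Golay smoothing, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitfusion import (
    GaitParams,
    KalmanModel,
    SGConfig,
    kalman_update,
    savgol_smooth,
    segment_windows,
    simulate_activity,
    unwrap_angles,
    wrap_angles,
)
from gaitfusion.preprocessing import savgol_coeffs_center


def _manual_kalman_step(A, H, Q, R, x, P, z):
    """Textbook matrix arithmetic of one predict+correct step."""
    x_prior = A @ x
    p_prior = A @ P @ A.T + Q
    k = p_prior @ H.T @ np.linalg.inv(H @ p_prior @ H.T + R)
    x_new = x_prior + k @ (z - H @ x_prior)
    p_new = (np.eye(len(x)) - k @ H) @ p_prior
    return x_new, p_new, k


class TestKalman:
    def test_zero_noise_limit_tracks_measurement(self):
        m = KalmanModel(A=[[1.0]], H=[[1.0]], Q=[[0.0]], R=[[1e-12]],
                        x=[0.0], P=[[1.0]])
        m = kalman_update(m, 5.0)
        assert m.x[0] == pytest.approx(5.0, abs=1e-6)

    def test_uninformative_measurement_leaves_state(self):
        m = KalmanModel(A=[[1.0]], H=[[1.0]], Q=[[0.0]], R=[[1e12]],
                        x=[2.0], P=[[1.0]])
        m = kalman_update(m, 100.0)
        assert m.x[0] == pytest.approx(2.0, abs=1e-6)

    def test_two_state_model_matches_matrix_oracle(self):
        rng = np.random.default_rng(3)
        A = np.eye(2) + 0.1 * rng.standard_normal((2, 2))
        H = rng.standard_normal((2, 2))
        Q = np.diag([0.1, 0.2])
        R = np.diag([0.5, 0.3])
        x = rng.standard_normal(2)
        P = np.eye(2)
        z = rng.standard_normal(2)
        model = kalman_update(KalmanModel(A=A, H=H, Q=Q, R=R, x=x, P=P), z)
        x_ref, p_ref, k_ref = _manual_kalman_step(A, H, Q, R, x, P, z)
        np.testing.assert_allclose(model.x, x_ref, rtol=1e-10)
        np.testing.assert_allclose(model.P, p_ref, rtol=1e-10)
        np.testing.assert_allclose(model.K, k_ref, rtol=1e-10)

    def test_p_trace_non_increasing_without_process_noise(self):
        m = KalmanModel(A=np.eye(2), H=np.eye(2), Q=np.zeros((2, 2)),
                        R=np.eye(2), x=np.zeros(2), P=np.eye(2))
        traces = [np.trace(m.P)]
        for z in np.random.default_rng(0).standard_normal((10, 2)):
            m = kalman_update(m, z)
            traces.append(np.trace(m.P))
        assert np.all(np.diff(traces) <= 1e-12)

    def test_singular_innovation_rejected(self):
        m = KalmanModel(A=[[1.0]], H=[[0.0]], Q=[[0.0]], R=[[0.0]],
                        x=[0.0], P=[[1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            kalman_update(m, 1.0)

    def test_inconsistent_dimensions_rejected(self):
        with pytest.raises(ValueError):
            KalmanModel(A=np.eye(2), H=np.eye(3), Q=np.zeros((2, 2)),
                        R=np.eye(3), x=np.zeros(2), P=np.eye(2))


class TestUnwrap:
    def test_wrap_crossing_hand_derivation(self):
        # delta = -358 < -180 raises the cycle counter to 1
        np.testing.assert_allclose(unwrap_angles([179.0, -179.0, -177.0]),
                                   [179.0, 181.0, 183.0])

    def test_no_crossing_unchanged(self):
        np.testing.assert_allclose(unwrap_angles([10.0, 20.0, 30.0]),
                                   [10.0, 20.0, 30.0])
        np.testing.assert_allclose(unwrap_angles([5.0] * 4), [5.0] * 4)

    def test_empty_sequence(self):
        assert unwrap_angles(np.array([])).size == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=-179.999, max_value=180.0), min_size=2,
                    max_size=100))
    def test_continuity_and_exact_invertibility(self, raw):
        raw = np.asarray(raw)
        corr = unwrap_angles(raw)
        # wrapping back recovers the raw sequence exactly
        np.testing.assert_allclose(wrap_angles(corr), raw, atol=1e-9)
        # cycle counter is an exact multiple of 360
        k = (corr - raw) / 360.0
        np.testing.assert_allclose(k, np.round(k), atol=1e-12)

    def test_continuous_rotation_has_no_jumps(self):
        true = np.linspace(0, 1000, 400)  # nearly 3 turns
        corr = unwrap_angles(wrap_angles(true))
        assert np.all(np.abs(np.diff(corr)) <= 180.0)
        np.testing.assert_allclose(corr, true, atol=1e-9)


class TestSavitzkyGolay:
    def test_constant_signal_unchanged(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(savgol_smooth(x), x, atol=1e-12)

    def test_polynomial_of_filter_degree_reproduced(self):
        t = np.linspace(-1, 1, 60)
        x = 2.0 - t + 0.5 * t**2
        sm = savgol_smooth(x, SGConfig(half_width=5, degree=2))
        np.testing.assert_allclose(sm, x, atol=1e-10)

    def test_cubic_reproduced_including_edges(self):
        t = np.arange(40, dtype=float)
        x = 1.0 + t - 0.1 * t**2 + 0.002 * t**3
        sm = savgol_smooth(x, SGConfig(half_width=5, degree=3))
        np.testing.assert_allclose(sm, x, rtol=1e-9)

    def test_coefficients_match_normal_equation_oracle(self):
        cfg = SGConfig(half_width=4, degree=3)
        offsets = np.arange(-4, 5, dtype=float)
        a = np.vander(offsets, 4, increasing=True)
        oracle = (np.linalg.inv(a.T @ a) @ a.T)[0]
        np.testing.assert_allclose(savgol_coeffs_center(cfg), oracle,
                                   rtol=1e-10)

    def test_random_window_matches_brute_force_fit(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(31)
        cfg = SGConfig(half_width=6, degree=3)
        sm = savgol_smooth(x, cfg)
        # brute-force: solve (A'A)a = A'X on the centered window at i=15
        offsets = np.arange(-6, 7, dtype=float)
        a = np.vander(offsets, 4, increasing=True)
        coef = np.linalg.solve(a.T @ a, a.T @ x[9:22])
        assert sm[15] == pytest.approx(coef[0], rel=1e-10)

    def test_interior_agrees_with_scipy_reference(self):
        from scipy.signal import savgol_filter
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        cfg = SGConfig(half_width=5, degree=3)
        ours = savgol_smooth(x, cfg)
        ref = savgol_filter(x, 11, 3)
        np.testing.assert_allclose(ours[5:-5], ref[5:-5], rtol=1e-9)

    def test_degree_must_be_below_window_length(self):
        with pytest.raises(ValueError):
            SGConfig(half_width=2, degree=5)

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(5), SGConfig(half_width=5, degree=3))


class TestWindows:
    def test_150s_recording_yields_465_windows(self):
        rec = simulate_activity(GaitParams.for_activity("walking"), 150,
                                seed=0)
        assert rec.n_frames == 15000
        assert len(segment_windows(rec)) == 465

    def test_single_window_recording(self):
        rec = simulate_activity(GaitParams.for_activity("standing"), 1.28,
                                seed=0)
        windows = segment_windows(rec)
        assert len(windows) == 1
        assert windows[0].size == 128

    def test_consecutive_windows_share_96_samples(self, walking_windows):
        w0, w1 = walking_windows[0], walking_windows[1]
        assert w1.start - w0.start == 32
        np.testing.assert_array_equal(w0.pressure[:, 32:], w1.pressure[:, :96])

    def test_short_recording_warns_and_returns_empty(self):
        rec = simulate_activity(GaitParams.for_activity("standing"), 1.0,
                                seed=0)
        with pytest.warns(UserWarning):
            assert segment_windows(rec) == []

    def test_majority_label_with_tie_toward_earlier(self):
        from gaitfusion.preprocessing import _majority_label
        labels = np.array(["sitting"] * 64 + ["sit_to_stand"] * 64)
        assert _majority_label(labels) == "sitting"
        labels = np.array(["sitting"] * 60 + ["sit_to_stand"] * 68)
        assert _majority_label(labels) == "sit_to_stand"
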