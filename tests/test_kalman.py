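import json

import numpy as np
import pytest

from reachbench.kalman import (
    KalmanModel,
    decode_segments,
    fit_kalman,
    fit_kalman_pairs,
    kalman_decode,
)


def _random_model(rng, d=2, c=6, w=0.05, q=0.5):
    A = rng.normal(size=(d, d))
    A *= 0.9 / np.max(np.abs(np.linalg.eigvals(A)))
    H = rng.normal(size=(c, d))
    return KalmanModel(A=A, W=w * np.eye(d), H=H, Q=q * np.eye(c),
                       initial_state=np.zeros(d), initial_covariance=np.eye(d))


def _simulate(model, T, rng):
    d, c = model.state_dim, model.n_channels
    Lw = np.linalg.cholesky(model.W + 1e-12 * np.eye(d))
    Lq = np.linalg.cholesky(model.Q + 1e-12 * np.eye(c))
    x = np.zeros(d)
    states, obs = [], []
    for _ in range(T):
        x = model.A @ x + Lw @ rng.normal(size=d)
        states.append(x)
        obs.append(model.H @ x + Lq @ rng.normal(size=c))
    return np.array(states), np.array(obs)


class TestFit:
    def test_recovers_transition_matrix_noiseless(self, rng):
        A_true = np.array([[0.9, 0.1], [-0.2, 0.8]])
        x = np.empty((200, 2))
        x[0] = [1.0, -0.5]
        for t in range(1, 200):
            x[t] = A_true @ x[t - 1]
        model = fit_kalman(x, rng.normal(size=(200, 3)))
        assert np.max(np.abs(model.A - A_true)) < 1e-8
        assert np.max(np.abs(model.W)) < 1e-12

    def test_recovers_observation_matrix_noiseless(self, rng):
        x = rng.normal(size=(300, 2))
        H_true = rng.normal(size=(5, 2))
        model = fit_kalman(x, x @ H_true.T)
        assert np.max(np.abs(model.H - H_true)) < 1e-8
        assert np.max(np.abs(model.Q)) < 1e-12

    def test_white_noise_states_have_no_dynamics(self, rng):
        T = 4000
        x = rng.normal(size=(T, 1))
        model = fit_kalman(x, rng.normal(size=(T, 2)))
        assert abs(model.A[0, 0]) < 3 / np.sqrt(T)

    def test_centered_fit_recovers_dynamics_around_offset(self, rng):
        A_true = np.array([[0.95, 0.0], [0.1, 0.9]])
        mu = np.array([10.0, -4.0])
        x = np.empty((300, 2))
        x[0] = mu + [1.0, 1.0]
        for t in range(1, 300):
            x[t] = mu + A_true @ (x[t - 1] - mu)
        H_true = rng.normal(size=(4, 2))
        z_offset = np.array([5.0, 5.0, 5.0, 5.0])
        z = (x - mu) @ H_true.T + z_offset
        model = fit_kalman(x, z, center=True)
        # the empirical mean differs from mu by the decaying transient,
        # so recovery is close but not exact
        assert np.max(np.abs(model.A - A_true)) < 1e-3

    def test_pairs_exclude_segment_boundaries(self, rng):
        # a jump between segments must not contaminate the dynamics fit
        seg1 = np.cumsum(rng.normal(size=(100, 1)), axis=0)
        seg2 = seg1[-1] + 1000.0 + np.cumsum(rng.normal(size=(100, 1)), axis=0)
        z1, z2 = rng.normal(size=(100, 2)), rng.normal(size=(100, 2))
        split = fit_kalman_pairs([seg1, seg2], [z1, z2])
        joined = fit_kalman(np.vstack([seg1, seg2]), np.vstack([z1, z2]))
        assert split.W[0, 0] < joined.W[0, 0]

    def test_warns_on_singular_gram(self, rng):
        x = np.zeros((50, 2))
        x[:, 0] = rng.normal(size=50)  # second state identically zero
        with pytest.warns(UserWarning, match="minimum-norm"):
            fit_kalman(x, rng.normal(size=(50, 2)))


class TestDecode:
    def test_noiseless_identity_posterior_equals_observations(self):
        model = KalmanModel(A=[[1.0]], W=[[0.0]], H=[[1.0]], Q=[[0.0]],
                            initial_state=[0.0], initial_covariance=[[1.0]])
        z = np.array([[0.3], [-1.2], [2.5], [0.0]])
        seq = kalman_decode(model, z, method="standard")
        np.testing.assert_allclose(seq.states, z, atol=1e-9)

    def test_two_step_scalar_recursion_matches_hand_oracle(self):
        A, W, H, Q = 1.0, 0.01, 1.0, 1.0
        x0, P0 = 0.0, 1.0
        z = [1.0, 1.0]
        # hand recursion in plain floats
        x, P = x0, P0
        expected = []
        for zt in z:
            x_pred = A * x
            P_pred = A * P * A + W
            S = H * P_pred * H + Q
            K = P_pred * H / S
            x = x_pred + K * (zt - H * x_pred)
            P = (1 - K * H) * P_pred
            expected.append(x)
        model = KalmanModel(A=[[A]], W=[[W]], H=[[H]], Q=[[Q]],
                            initial_state=[x0], initial_covariance=[[P0]])
        seq = kalman_decode(model, np.array(z)[:, None], method="standard")
        np.testing.assert_allclose(seq.states[:, 0], expected, atol=1e-12)

    def test_decode_beats_pseudo_inverse_baseline(self, rng):
        model = _random_model(rng)
        states, obs = _simulate(model, 500, rng)
        decoded = kalman_decode(model, obs).states
        pinv_states = obs @ np.linalg.pinv(model.H).T
        rmse_kf = np.sqrt(np.mean((decoded - states) ** 2))
        rmse_pinv = np.sqrt(np.mean((pinv_states - states) ** 2))
        assert rmse_kf < rmse_pinv

    def test_large_q_tends_to_prior_prediction(self, rng):
        model = _random_model(rng, c=2)
        _, obs = _simulate(model, 50, rng)
        big_q = KalmanModel(A=model.A, W=model.W, H=model.H,
                            Q=model.Q * 1e6, initial_state=model.initial_state,
                            initial_covariance=model.initial_covariance)
        seq = kalman_decode(big_q, obs, method="standard").states
        # pure prior propagation from the initial state
        x = model.initial_state.copy()
        prior = []
        for _ in range(len(obs)):
            x = model.A @ x
            prior.append(x.copy())
        np.testing.assert_allclose(seq, np.array(prior), atol=1e-3)

    def test_small_q_tends_to_observation_inverse(self, rng):
        base = _random_model(rng, d=2, c=2)
        # well-conditioned observation matrix so the inverse is stable
        model = KalmanModel(A=base.A, W=base.W,
                            H=np.array([[2.0, 0.3], [-0.4, 1.5]]),
                            Q=base.Q, initial_state=base.initial_state,
                            initial_covariance=base.initial_covariance)
        states, obs = _simulate(model, 50, rng)
        small_q = KalmanModel(A=model.A, W=model.W, H=model.H,
                              Q=model.Q * 1e-6, initial_state=model.initial_state,
                              initial_covariance=model.initial_covariance)
        seq = kalman_decode(small_q, obs, method="standard").states
        inverse = obs @ np.linalg.inv(model.H).T
        np.testing.assert_allclose(seq[5:], inverse[5:], atol=1e-2)

    def test_single_step_matches_closed_form_gain(self, rng):
        model = _random_model(rng, d=3, c=4)
        z = rng.normal(size=(1, 4))
        seq = kalman_decode(model, z, method="standard")
        x_pred = model.A @ model.initial_state
        P_pred = model.A @ model.initial_covariance @ model.A.T + model.W
        S = model.H @ P_pred @ model.H.T + model.Q
        K = P_pred @ model.H.T @ np.linalg.inv(S)
        expected = x_pred + K @ (z[0] - model.H @ x_pred)
        np.testing.assert_allclose(seq.states[0], expected, atol=1e-10)

    def test_information_form_equals_standard_form(self, rng):
        model = _random_model(rng, d=3, c=12)
        _, obs = _simulate(model, 200, rng)
        a = kalman_decode(model, obs, method="standard").states
        b = kalman_decode(model, obs, method="information").states
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_covariances_symmetric_psd(self, rng):
        model = _random_model(rng)
        _, obs = _simulate(model, 100, rng)
        seq = kalman_decode(model, obs, return_covariances=True)
        for P in seq.covariances:
            np.testing.assert_allclose(P, P.T, atol=1e-12)
            assert np.min(np.linalg.eigvalsh(P)) > -1e-10

    def test_adding_channels_never_increases_posterior_covariance(self, rng):
        base = _random_model(rng, d=2, c=4)
        extra_H = np.vstack([base.H, rng.normal(size=(2, 2))])
        extra_Q = np.block([
            [base.Q, np.zeros((4, 2))],
            [np.zeros((2, 4)), 0.3 * np.eye(2)],
        ])
        bigger = KalmanModel(A=base.A, W=base.W, H=extra_H, Q=extra_Q,
                             initial_state=base.initial_state,
                             initial_covariance=base.initial_covariance)
        states, obs = _simulate(bigger, 100, rng)
        seq_small = kalman_decode(base, obs[:, :4], return_covariances=True,
                                  method="standard")
        seq_big = kalman_decode(bigger, obs, return_covariances=True,
                                method="standard")
        tr_small = np.trace(seq_small.covariances, axis1=1, axis2=2)
        tr_big = np.trace(seq_big.covariances, axis1=1, axis2=2)
        assert np.all(tr_big <= tr_small + 1e-10)

    def test_segmented_decode_reinitializes(self, rng):
        model = _random_model(rng)
        _, obs = _simulate(model, 100, rng)
        parts = decode_segments(model, obs, [(0, 50), (50, 100)])
        whole_first = kalman_decode(model, obs[:50]).states
        np.testing.assert_allclose(parts[0].states, whole_first)
        fresh = kalman_decode(model, obs[50:]).states
        np.testing.assert_allclose(parts[1].states, fresh)

    def test_rejects_channel_mismatch(self, rng):
        model = _random_model(rng, c=4)
        with pytest.raises(ValueError, match="channels"):
            kalman_decode(model, rng.normal(size=(10, 3)))


class TestModelValidation:
    def test_rejects_non_psd_noise(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            KalmanModel(A=[[1.0]], W=[[-1.0]], H=[[1.0]], Q=[[1.0]])

    def test_json_round_trip(self, rng, tmp_path):
        model = _random_model(rng)
        path = tmp_path / "kf.json"
        model.to_json(path)
        back = KalmanModel.from_json(path)
        for attr in ("A", "W", "H", "Q", "initial_state", "initial_covariance",
                     "state_mean", "observation_mean"):
            np.testing.assert_allclose(getattr(back, attr), getattr(model, attr))
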