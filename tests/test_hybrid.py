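import numpy as np
import pytest

from reachbench.hybrid import (
    HybridModel,
    MLPSpeedFilter,
    build_hybrid_states,
    fit_hybrid,
    hybrid_decode,
    mlp_forward,
    scaled_conjugate_gradient,
    train_speed_mlp,
)
from reachbench.synthetic import gen_minimum_jerk_reach


class TestBuildHybridStates:
    def test_constant_velocity(self):
        v = np.tile([1.0, 0.0], (5, 1))
        states, target, valid = build_hybrid_states(v)
        np.testing.assert_allclose(states, np.tile([1, 1, 1, 1, 0], (5, 1)))
        np.testing.assert_allclose(target, np.ones(5))
        assert not valid[:2].any() and valid[2:].all()

    def test_speed_ramp_lag_bookkeeping(self):
        v = np.column_stack([np.arange(4.0), np.zeros(4)])
        states, _, _ = build_hybrid_states(v)
        np.testing.assert_allclose(states[3, :3], [3.0, 2.0, 1.0])

    def test_lagged_column_is_shifted_copy(self, rng):
        v = rng.normal(size=(100, 2))
        states, _, _ = build_hybrid_states(v)
        np.testing.assert_array_equal(states[1:, 1], states[:-1, 0])
        np.testing.assert_array_equal(states[2:, 2], states[1:-1, 1])

    def test_rest_direction_zeroed_by_default(self):
        v = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        states, _, _ = build_hybrid_states(v)
        np.testing.assert_allclose(states[1, 3:5], [0.0, 0.0])

    def test_rest_direction_carry_option(self):
        v = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        states, _, _ = build_hybrid_states(v, direction_at_rest="carry")
        np.testing.assert_allclose(states[1, 3:5], [1.0, 0.0])

    def test_unit_norm_directions_when_always_moving(self, rng):
        angles = rng.uniform(0, 2 * np.pi, size=50)
        v = 3.0 * np.column_stack([np.cos(angles), np.sin(angles)])
        states, _, _ = build_hybrid_states(v)
        np.testing.assert_allclose(np.linalg.norm(states[:, 3:5], axis=1),
                                   np.ones(50), atol=1e-9)


class TestMLPForward:
    def test_output_strictly_within_speed_scale(self, rng):
        mlp = _random_mlp(rng, scale=30.0)
        out = mlp.forward(rng.normal(scale=40.0, size=(200, 3)))
        assert np.all(out > 0.0) and np.all(out < 30.0)

    def test_zero_weights_give_half_scale(self):
        mlp = MLPSpeedFilter(W1=np.zeros((18, 3)), b1=np.zeros(18),
                             w2=np.zeros(18), b2=0.0, speed_scale=10.0)
        out = mlp.forward(np.array([[1.0, 2.0, 3.0]]))
        assert out[0] == pytest.approx(5.0)

    def test_matches_independent_matrix_arithmetic(self, rng):
        mlp = _random_mlp(rng, scale=7.0)
        X = rng.normal(size=(20, 3))
        # independent re-implementation of the forward pass
        Xs = X / mlp.speed_scale
        expected = np.empty(20)
        for i in range(20):
            hidden = np.tanh(mlp.W1 @ Xs[i] + mlp.b1)
            logit = float(mlp.w2 @ hidden + mlp.b2)
            expected[i] = 1.0 / (1.0 + np.exp(-logit)) * mlp.speed_scale
        np.testing.assert_allclose(mlp_forward(mlp, X), expected, atol=1e-12)


def _random_mlp(rng, scale):
    return MLPSpeedFilter(W1=rng.normal(size=(18, 3)), b1=rng.normal(size=18),
                          w2=rng.normal(size=18), b2=float(rng.normal()),
                          speed_scale=scale)


def _bell_dataset(rng, n_trials=40):
    """Speed-state triplets + noisy current-speed targets from bell profiles."""
    states, targets = [], []
    for _ in range(n_trials):
        reach = gen_minimum_jerk_reach((0, 0), (10, 0), 0.9, 50.0)
        speed = reach.speed
        s, t, _ = build_hybrid_states(reach.velocity)
        noisy = s[:, :3] + rng.normal(scale=2.0, size=(len(s), 3))
        states.append(noisy)
        targets.append(speed)
    return np.vstack(states), np.concatenate(targets)


class TestTrainSpeedMLP:
    def test_constant_targets_learned_with_explicit_scale(self, rng):
        X = rng.normal(size=(500, 3))
        scale = 4.0
        y = np.full(500, 0.5 * scale)
        mlp = train_speed_mlp(X, y, seed=0, speed_scale=scale)
        out = mlp.forward(X)
        assert np.max(np.abs(out / scale - 0.5)) < 0.01

    def test_rejects_zero_variance_targets_without_scale(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            train_speed_mlp(rng.normal(size=(50, 3)), np.full(50, 2.0))

    def test_rejects_negative_targets(self, rng):
        with pytest.raises(ValueError, match="nonnegative"):
            train_speed_mlp(rng.normal(size=(50, 3)), -np.ones(50))

    def test_beats_linear_regression_on_bell_profiles(self, rng):
        X, y = _bell_dataset(rng)
        mlp = train_speed_mlp(X, y, seed=1)
        mlp_mse = np.mean((mlp.forward(X) - y) ** 2)
        A = np.column_stack([X, np.ones(len(X))])
        w, *_ = np.linalg.lstsq(A, y, rcond=None)
        lin_mse = np.mean((A @ w - y) ** 2)
        assert mlp_mse < lin_mse

    def test_same_seed_same_weights(self, rng):
        X, y = _bell_dataset(rng, n_trials=10)
        m1 = train_speed_mlp(X, y, seed=7)
        m2 = train_speed_mlp(X, y, seed=7)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.w2, m2.w2)
        assert m1.b2 == m2.b2

    def test_loss_history_non_increasing(self, rng):
        X, y = _bell_dataset(rng, n_trials=10)
        mlp = train_speed_mlp(X, y, seed=2)
        assert np.all(np.diff(mlp.loss_history) <= 0)


def test_scg_minimizes_quadratic():
    # f(w) = 0.5 w^T D w with known minimum at 0
    D = np.diag([1.0, 10.0, 100.0])

    def fg(w):
        return 0.5 * float(w @ D @ w), D @ w

    w, history = scaled_conjugate_gradient(fg, np.array([1.0, 1.0, 1.0]),
                                           max_iter=200)
    assert history[-1] < 1e-12
    assert np.max(np.abs(w)) < 1e-5


def _training_session(rng, T=1500):
    """Always-moving velocity plus observations linear in the hybrid state."""
    angles = np.cumsum(rng.normal(scale=0.1, size=T))
    speed = 2.0 + np.sin(np.linspace(0, 20, T)) ** 2
    v = speed[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    states, _, _ = build_hybrid_states(v)
    H_true = rng.normal(size=(12, 5))
    obs = states @ H_true.T
    return v, obs, H_true


class TestFitHybrid:
    def test_noiseless_observation_matrix_recovered(self, rng):
        v, obs, H_true = _training_session(rng)
        model = fit_hybrid(v, obs, seed=0, center=False, max_iter=50)
        assert np.max(np.abs(model.kalman.H - H_true)) < 1e-6

    def test_refit_same_seed_identical(self, rng):
        v, obs, _ = _training_session(rng, T=600)
        m1 = fit_hybrid(v, obs, seed=5, max_iter=100)
        m2 = fit_hybrid(v, obs, seed=5, max_iter=100)
        assert m1.to_json() == m2.to_json()

    def test_structured_transition_rows_are_lag_shifts(self, rng):
        v, obs, _ = _training_session(rng, T=600)
        model = fit_hybrid(v, obs, seed=0, structured_A=True, max_iter=20)
        np.testing.assert_allclose(model.kalman.A[1], [1, 0, 0, 0, 0])
        np.testing.assert_allclose(model.kalman.A[2], [0, 1, 0, 0, 0])

    def test_mlp_receives_only_speed_states(self, rng):
        v, obs, _ = _training_session(rng, T=600)
        model = fit_hybrid(v, obs, seed=0, max_iter=20)
        assert model.mlp.input_dim == 3

    def test_teacher_forcing_option(self, rng):
        v, obs, _ = _training_session(rng, T=600)
        model = fit_hybrid(v, obs, seed=0, mlp_inputs="true", max_iter=100)
        assert model.config["mlp_inputs"] == "true"


class TestHybridDecode:
    def test_direction_unit_norm_and_speed_bounded(self, rng):
        v, obs, _ = _training_session(rng)
        model = fit_hybrid(v, obs, seed=0, max_iter=100)
        res = hybrid_decode(model, obs + rng.normal(scale=0.1, size=obs.shape))
        np.testing.assert_allclose(np.linalg.norm(res.direction, axis=1),
                                   np.ones(len(obs)), atol=1e-9)
        assert np.all(res.speed > 0)
        assert np.all(res.speed <= model.mlp.speed_scale)

    def test_ablation_shares_identical_posteriors(self, rng):
        v, obs, _ = _training_session(rng, T=800)
        model = fit_hybrid(v, obs, seed=0, max_iter=50)
        full = hybrid_decode(model, obs, speed_readout="mlp")
        ablation = hybrid_decode(model, obs, speed_readout="state")
        np.testing.assert_array_equal(full.states, ablation.states)
        np.testing.assert_array_equal(full.direction, ablation.direction)
        assert np.all(ablation.speed >= 0)

    def test_velocity_is_speed_times_direction(self, rng):
        v, obs, _ = _training_session(rng, T=600)
        model = fit_hybrid(v, obs, seed=0, max_iter=50)
        res = hybrid_decode(model, obs)
        np.testing.assert_allclose(res.velocity,
                                   res.speed[:, None] * res.direction,
                                   atol=1e-12)

    def test_json_round_trip(self, rng, tmp_path):
        v, obs, _ = _training_session(rng, T=600)
        model = fit_hybrid(v, obs, seed=0, max_iter=20)
        path = tmp_path / "hybrid.json"
        model.to_json(path)
        back = HybridModel.from_json(path)
        res_a = hybrid_decode(model, obs[:100])
        res_b = hybrid_decode(back, obs[:100])
        np.testing.assert_allclose(res_a.velocity, res_b.velocity, atol=1e-12)
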