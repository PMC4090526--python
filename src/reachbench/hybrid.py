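"""Hybrid Kalman decoder: independent speed and direction estimation.

Point-to-point hand movements have a bell-shaped, nonlinear speed
profile that is largely independent of movement direction.  The hybrid
decoder exploits this by augmenting the Kalman state with three speed
variables and reading speed and direction out separately:

    x(t) = [r(t), r(t-1), r(t-2), d_x(t), d_y(t)]^T

where ``r`` is the hand speed and ``(d_x, d_y)`` the unit movement
direction.  A 5-dim Kalman filter (identified by least squares, exactly
as the standard decoder) produces a posterior state per sample.  The
direction read-out normalizes the posterior ``(d_x, d_y)`` to unit
length (carrying the previous direction forward when the posterior
vector is degenerate).  The speed read-out is a small multilayer
perceptron — 3 inputs, 18 tanh hidden units, one logistic-sigmoid
output — mapping the three posterior speed states to the current speed;
its bounded output (scaled by the training speed ceiling) keeps decoded
speeds nonnegative and within the trained range.  The decoded velocity
is speed x direction.  The MLP output never feeds back into the Kalman
recursion, which stays linear-Gaussian.

The ablation variant reads speed directly from the posterior ``r(t)``
(clipped at zero) instead of the MLP; both variants share the exact
same Kalman posterior sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kalman import KalmanModel, StateSequence, fit_kalman, fit_kalman_pairs, kalman_decode
from .kinematics import DEFAULT_SPEED_FLOOR, FALLBACK_DIRECTION, decompose_velocity

logger = logging.getLogger(__name__)

__all__ = [
    "MLPSpeedFilter",
    "HybridModel",
    "HybridDecodeResult",
    "build_hybrid_states",
    "train_speed_mlp",
    "mlp_forward",
    "fit_hybrid",
    "hybrid_decode",
]


def build_hybrid_states(
    velocity: np.ndarray,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
    direction_at_rest: str = "zero",
):
    """Build the 5-dim speed/direction state sequence from true velocity.

    Returns ``(states, target_speed, valid)``: states are
    ``[r(t), r(t-1), r(t-2), d_x, d_y]`` per row with the two lagged
    speed columns edge-replicated (and flagged invalid) at the start,
    ``target_speed`` is the current speed ``r(t)``, and ``valid`` marks
    rows with complete lag history.

    ``direction_at_rest`` sets the direction components at samples whose
    speed does not exceed ``speed_floor``:

    - ``"zero"`` (default): a null direction — the movement direction is
      treated as absent while the hand is still, which keeps the
      observation fit from associating neural baseline with a stale
      direction and lets the system model learn that direction collapses
      between movements;
    - ``"carry"``: the last valid direction carried forward (matching
      the decode-time normalization rule).
    """
    v = np.atleast_2d(np.asarray(velocity, dtype=float))
    if v.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sd = decompose_velocity(v, speed_floor)
    r = sd.speed
    direction = sd.direction
    if direction_at_rest == "zero":
        direction = direction.copy()
        direction[r <= speed_floor] = 0.0
    elif direction_at_rest != "carry":
        raise ValueError("direction_at_rest must be 'zero' or 'carry'")
    r1 = np.concatenate([r[:1], r[:-1]])
    r2 = np.concatenate([r[:1], r[:1], r[:-2]])
    states = np.column_stack([r, r1, r2, direction])
    valid = np.arange(v.shape[0]) >= 2
    return states, r, valid


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class MLPSpeedFilter:
    """3 -> 18 (tanh) -> 1 (logistic) speed read-out network.

    Inputs are divided by ``speed_scale`` (the training speed ceiling)
    before the forward pass and the sigmoid output is multiplied by it,
    so predictions lie strictly in ``(0, speed_scale)``.
    """

    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    speed_scale: float
    rng_seed: int | None = None
    loss_history: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.b2 = float(self.b2)
        if self.W1.ndim != 2 or self.W1.shape[0] != self.b1.shape[0]:
            raise ValueError("W1 must be (hidden, input) with matching b1")
        if self.w2.shape != (self.W1.shape[0],):
            raise ValueError("w2 must have one weight per hidden unit")
        if self.speed_scale <= 0:
            raise ValueError("speed_scale must be positive")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_units(self) -> int:
        return self.W1.shape[0]

    def forward_scaled(self, X_scaled: np.ndarray) -> np.ndarray:
        """Forward pass in scaled units; output in (0, 1)."""
        hidden = np.tanh(X_scaled @ self.W1.T + self.b1)
        return _sigmoid(hidden @ self.w2 + self.b2)

    def forward(self, speed_states: np.ndarray) -> np.ndarray:
        """Predict speed (length-units/s) from speed-state rows."""
        X = np.atleast_2d(np.asarray(speed_states, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} inputs, got {X.shape[1]}")
        return self.forward_scaled(X / self.speed_scale) * self.speed_scale

    def to_dict(self) -> dict:
        return {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
            "speed_scale": self.speed_scale, "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MLPSpeedFilter":
        return cls(
            W1=np.array(payload["W1"]), b1=np.array(payload["b1"]),
            w2=np.array(payload["w2"]), b2=payload["b2"],
            speed_scale=payload["speed_scale"], rng_seed=payload.get("rng_seed"),
        )


def mlp_forward(mlp: MLPSpeedFilter, speed_state: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`MLPSpeedFilter.forward`."""
    return mlp.forward(speed_state)


def _pack(W1, b1, w2, b2):
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(w, hidden, n_in):
    i = hidden * n_in
    W1 = w[:i].reshape(hidden, n_in)
    b1 = w[i:i + hidden]
    w2 = w[i + hidden:i + 2 * hidden]
    b2 = w[-1]
    return W1, b1, w2, b2


def _mlp_loss_grad(w, X, y, hidden):
    """Half mean-squared error of the scaled network and its gradient."""
    n_in = X.shape[1]
    W1, b1, w2, b2 = _unpack(w, hidden, n_in)
    a1 = np.tanh(X @ W1.T + b1)
    out = _sigmoid(a1 @ w2 + b2)
    err = out - y
    loss = 0.5 * float(np.mean(err ** 2))
    n = X.shape[0]
    d2 = err * out * (1.0 - out) / n
    gw2 = a1.T @ d2
    gb2 = d2.sum()
    d1 = (d2[:, None] * w2[None, :]) * (1.0 - a1 ** 2)
    gW1 = d1.T @ X
    gb1 = d1.sum(axis=0)
    return loss, _pack(gW1, gb1, gw2, gb2)


def scaled_conjugate_gradient(
    fun_grad, w0: np.ndarray, max_iter: int = 500, grad_tol: float = 1e-6,
    sigma: float = 1e-4, lambda0: float = 1e-6,
):
    """Minimize a differentiable objective with Moller's SCG algorithm.

    A Hessian-free conjugate-gradient method: curvature along the search
    direction is approximated by a finite difference of gradients and a
    Levenberg-Marquardt style scale ``lambda`` keeps the quadratic model
    trusted.  Returns ``(w, loss_history)`` where the history holds the
    objective after each accepted step (non-increasing by construction).
    """
    w = w0.copy()
    n = w.size
    f, g = fun_grad(w)
    r = -g
    p = r.copy()
    success = True
    lam, lam_bar = lambda0, 0.0
    history = [f]
    delta = 0.0

    for k in range(1, max_iter + 1):
        if np.linalg.norm(r) <= grad_tol:
            break
        p_sq = float(p @ p)
        if p_sq == 0.0:
            break
        if success:
            sigma_k = sigma / np.sqrt(p_sq)
            _, g_eps = fun_grad(w + sigma_k * p)
            s = (g_eps - g) / sigma_k
            delta = float(p @ s)
        delta_k = delta + (lam - lam_bar) * p_sq
        if delta_k <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta_k / p_sq)
            delta_k = -delta_k + lam * p_sq
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta_k
        f_new, g_new = fun_grad(w + alpha * p)
        comparison = 2.0 * delta_k * (f - f_new) / mu ** 2
        if comparison >= 0:  # successful reduction
            w = w + alpha * p
            f = f_new
            g = g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            history.append(f)
            if k % n == 0:  # restart the direction periodically
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(0.5 * lam, 1e-18)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            # shrink the trusted step multiplicatively so repeated failures
            # cannot stall at a constant step size
            lam = 4.0 * lam
        if lam > 1e20:  # no trustable step remains
            break
    return w, np.array(history)


def train_speed_mlp(
    speed_states: np.ndarray,
    target_speed: np.ndarray,
    hidden_units: int = 18,
    seed: int = 0,
    max_iter: int = 500,
    grad_tol: float = 1e-6,
    speed_scale: float | None = None,
) -> MLPSpeedFilter:
    """Train the nonlinear speed filter with scaled conjugate gradient.

    Inputs and targets are normalized by ``speed_scale`` (default: the
    maximum training speed) so the logistic output covers the observed
    speed range.  Weights are initialized uniform(-0.5, 0.5)/sqrt(fan_in)
    from the given seed; identical data and seed give identical weights.
    """
    X = np.atleast_2d(np.asarray(speed_states, dtype=float))
    y = np.asarray(target_speed, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("speed_states and target_speed must be aligned")
    if np.any(y < 0):
        raise ValueError("target speeds must be nonnegative")
    if speed_scale is None:
        if float(np.var(y)) == 0.0:
            raise ValueError(
                "zero-variance targets: cannot infer a speed scale "
                "(pass speed_scale explicitly)"
            )
        speed_scale = float(np.max(y))
    if speed_scale <= 0:
        raise ValueError("speed_scale must be positive")

    n_in = X.shape[1]
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-0.5, 0.5, size=(hidden_units, n_in)) / np.sqrt(n_in)
    b1 = rng.uniform(-0.5, 0.5, size=hidden_units) / np.sqrt(n_in)
    w2 = rng.uniform(-0.5, 0.5, size=hidden_units) / np.sqrt(hidden_units)
    b2 = rng.uniform(-0.5, 0.5) / np.sqrt(hidden_units)

    Xs, ys = X / speed_scale, y / speed_scale
    w0 = _pack(W1, b1, w2, b2)
    w_opt, history = scaled_conjugate_gradient(
        lambda w: _mlp_loss_grad(w, Xs, ys, hidden_units),
        w0, max_iter=max_iter, grad_tol=grad_tol,
    )
    W1, b1, w2, b2 = _unpack(w_opt, hidden_units, n_in)
    return MLPSpeedFilter(W1=W1, b1=b1, w2=w2, b2=b2, speed_scale=speed_scale,
                          rng_seed=seed, loss_history=history)


@dataclass
class HybridModel:
    """5-dim Kalman model plus the MLP speed read-out."""

    kalman: KalmanModel
    mlp: MLPSpeedFilter
    speed_floor: float = DEFAULT_SPEED_FLOOR
    ablation: bool = False
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kalman.state_dim != 5:
            raise ValueError("hybrid Kalman state must be 5-dimensional")
        if self.mlp.input_dim != 3:
            raise ValueError("speed MLP must take exactly the 3 speed states")

    def to_json(self, path=None) -> str:
        payload = {
            "model": "hybrid_kalman",
            "kalman": json.loads(self.kalman.to_json()),
            "mlp": self.mlp.to_dict(),
            "speed_floor": self.speed_floor,
            "ablation": self.ablation,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "HybridModel":
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            payload = json.loads(Path(text).read_text())
        return cls(
            kalman=KalmanModel.from_json(json.dumps(payload["kalman"])),
            mlp=MLPSpeedFilter.from_dict(payload["mlp"]),
            speed_floor=payload["speed_floor"],
            ablation=payload["ablation"],
            config=payload.get("config", {}),
        )


@dataclass
class HybridDecodeResult:
    """Decoded velocity with its speed/direction decomposition."""

    velocity: np.ndarray
    speed: np.ndarray
    direction: np.ndarray
    states: np.ndarray


def fit_hybrid(
    velocity: np.ndarray,
    observations: np.ndarray,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
    hidden_units: int = 18,
    seed: int = 0,
    max_iter: int = 500,
    mlp_inputs: str = "posterior",
    structured_A: bool = False,
    direction_at_rest: str = "zero",
    center: bool = True,
    segments: list[tuple[int, int]] | None = None,
) -> HybridModel:
    """Identify the 5-dim Kalman model and train the speed MLP.

    The Kalman block is fit on ground-truth speed/direction states built
    from the training velocity (teacher forcing), exactly as the standard
    decoder.  ``mlp_inputs`` selects what the speed MLP sees during
    training:

    - ``"posterior"`` (default): the Kalman posterior speed states
      obtained by decoding the *training* observations — the MLP then
      learns to map noisy filtered states to the true speed, which is
      what it receives at decode time;
    - ``"true"``: the ground-truth speed states (pure teacher forcing).

    ``structured_A`` replaces the estimated rows for ``r(t-1)`` and
    ``r(t-2)`` with exact lag-shift bookkeeping.  ``segments`` (list of
    ``[start, stop)`` row ranges) restricts transition pairs so they never
    straddle a discontinuity (e.g. concatenated reach snippets).
    """
    v = np.atleast_2d(np.asarray(velocity, dtype=float))
    Z = np.atleast_2d(np.asarray(observations, dtype=float))
    if v.shape[0] != Z.shape[0]:
        raise ValueError("velocity and observations must be aligned")
    states, target_speed, _ = build_hybrid_states(
        v, speed_floor, direction_at_rest=direction_at_rest
    )

    if segments is None:
        kalman = fit_kalman(states, Z, center=center)
    else:
        kalman = fit_kalman_pairs(
            [states[s:e] for s, e in segments], [Z[s:e] for s, e in segments],
            center=center,
        )
    if structured_A:
        A = kalman.A.copy()
        A[1] = 0.0
        A[1, 0] = 1.0  # r(t-1) <- previous r(t)
        A[2] = 0.0
        A[2, 1] = 1.0  # r(t-2) <- previous r(t-1)
        kalman = KalmanModel(A=A, W=kalman.W, H=kalman.H, Q=kalman.Q,
                             initial_state=kalman.initial_state,
                             initial_covariance=kalman.initial_covariance,
                             state_mean=kalman.state_mean,
                             observation_mean=kalman.observation_mean)

    speed_scale = float(np.max(target_speed))
    if mlp_inputs == "true":
        mlp_X = states[:, :3]
    elif mlp_inputs == "posterior":
        if segments is None:
            posterior = kalman_decode(kalman, Z).states
        else:
            posterior = np.vstack(
                [kalman_decode(kalman, Z[s:e]).states for s, e in segments]
            )
            target_speed = np.concatenate([target_speed[s:e] for s, e in segments])
        mlp_X = posterior[:, :3]
    else:
        raise ValueError("mlp_inputs must be 'posterior' or 'true'")
    mlp = train_speed_mlp(mlp_X, target_speed, hidden_units=hidden_units,
                          seed=seed, max_iter=max_iter, speed_scale=speed_scale)
    return HybridModel(
        kalman=kalman, mlp=mlp, speed_floor=speed_floor,
        config={"mlp_inputs": mlp_inputs, "structured_A": structured_A,
                "direction_at_rest": direction_at_rest, "center": center,
                "hidden_units": hidden_units, "seed": seed, "max_iter": max_iter},
    )


def _normalize_directions(raw: np.ndarray, floor: float) -> np.ndarray:
    norms = np.linalg.norm(raw, axis=1)
    valid = norms > floor
    if not np.all(valid):
        logger.info("%d degenerate direction vector(s); carrying forward",
                    int(np.count_nonzero(~valid)))
    direction = np.tile(FALLBACK_DIRECTION, (raw.shape[0], 1))
    direction[valid] = raw[valid] / norms[valid, None]
    idx = np.maximum.accumulate(np.where(valid, np.arange(raw.shape[0]), -1))
    filled = idx >= 0
    direction[filled] = direction[idx[filled]]
    return direction


def hybrid_decode(
    model: HybridModel,
    observations: np.ndarray,
    segments: list[tuple[int, int]] | None = None,
    speed_readout: str | None = None,
) -> HybridDecodeResult:
    """Decode velocity as (MLP speed) x (unit direction) per sample.

    The 5-dim Kalman recursion runs on the observations alone (the MLP
    never feeds back).  ``speed_readout`` overrides the model's ablation
    flag: ``"mlp"`` uses the nonlinear filter, ``"state"`` reads the
    posterior ``r(t)`` directly (clipped at zero).  With ``segments`` the
    recursion re-initializes at each ``[start, stop)`` range.
    """
    Z = np.atleast_2d(np.asarray(observations, dtype=float))
    if segments is None:
        states = kalman_decode(model.kalman, Z).states
    else:
        states = np.vstack(
            [kalman_decode(model.kalman, Z[s:e]).states for s, e in segments]
        )
    if speed_readout is None:
        speed_readout = "state" if model.ablation else "mlp"
    if speed_readout == "mlp":
        speed = model.mlp.forward(states[:, :3])
        n_over = int(np.count_nonzero(states[:, 0] > model.mlp.speed_scale))
        if n_over:
            logger.info("%d posterior speed state(s) above the training "
                        "ceiling; sigmoid saturates", n_over)
    elif speed_readout == "state":
        speed = np.maximum(states[:, 0], 0.0)
    else:
        raise ValueError("speed_readout must be 'mlp' or 'state'")
    direction = _normalize_directions(states[:, 3:5], model.speed_floor)
    velocity = speed[:, None] * direction
    return HybridDecodeResult(velocity=velocity, speed=speed,
                              direction=direction, states=states)
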