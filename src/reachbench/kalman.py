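"""Standard Kalman filter decoder with least-squares system identification.

The generative model is linear-Gaussian and time-invariant:

    observation:  z(t) = H x(t) + eps(t),   eps ~ N(0, Q)
    system:       x(t) = A x(t-1) + nu(t),  nu  ~ N(0, W)

``fit_kalman`` estimates A and H by least squares from aligned training
states and observations, with W and Q as the residual covariances
(1/(T-1) normalization).  ``kalman_decode`` runs the usual two-step
recursion — predict from the system model, then update with the
innovation against the observed neural vector — over every observation.

For wide observation vectors (many channels, few states) the update is
carried out in information form with a precomputed Q^{-1}, which is
algebraically identical to the textbook gain formula but avoids a
channels x channels solve per step.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = ["KalmanModel", "StateSequence", "fit_kalman", "kalman_decode",
           "decode_segments"]


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


@dataclass
class KalmanModel:
    """Time-invariant linear-Gaussian state-space model."""

    A: np.ndarray
    W: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    initial_state: np.ndarray | None = None
    initial_covariance: np.ndarray | None = None
    state_mean: np.ndarray | None = None
    observation_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.W = _symmetrize(np.atleast_2d(np.asarray(self.W, dtype=float)))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.Q = _symmetrize(np.atleast_2d(np.asarray(self.Q, dtype=float)))
        d = self.A.shape[0]
        if self.A.shape != (d, d) or self.W.shape != (d, d):
            raise ValueError("A and W must be square with matching size")
        if self.H.shape[1] != d or self.Q.shape != (self.H.shape[0],) * 2:
            raise ValueError("H must be (channels, state_dim); Q (channels, channels)")
        if self.initial_state is None:
            self.initial_state = np.zeros(d)
        else:
            self.initial_state = np.asarray(self.initial_state, dtype=float).reshape(d)
        if self.initial_covariance is None:
            self.initial_covariance = self.W.copy()
        else:
            self.initial_covariance = _symmetrize(
                np.asarray(self.initial_covariance, dtype=float).reshape(d, d)
            )
        if self.state_mean is None:
            self.state_mean = np.zeros(d)
        else:
            self.state_mean = np.asarray(self.state_mean, dtype=float).reshape(d)
        if self.observation_mean is None:
            self.observation_mean = np.zeros(self.H.shape[0])
        else:
            self.observation_mean = np.asarray(
                self.observation_mean, dtype=float
            ).reshape(self.H.shape[0])
        for M, name in ((self.W, "W"), (self.Q, "Q")):
            if np.min(np.linalg.eigvalsh(M)) < -1e-8 * max(1.0, np.abs(M).max()):
                raise ValueError(f"{name} must be positive semidefinite")

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    @property
    def n_channels(self) -> int:
        return self.H.shape[0]

    def to_json(self, path=None) -> str:
        payload = {
            "model": "kalman",
            "state_dim": self.state_dim,
            "n_channels": self.n_channels,
            "A": self.A.tolist(),
            "W": self.W.tolist(),
            "H": self.H.tolist(),
            "Q": self.Q.tolist(),
            "initial_state": self.initial_state.tolist(),
            "initial_covariance": self.initial_covariance.tolist(),
            "state_mean": self.state_mean.tolist(),
            "observation_mean": self.observation_mean.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "KalmanModel":
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            payload = json.loads(Path(text).read_text())
        return cls(
            A=np.array(payload["A"]), W=np.array(payload["W"]),
            H=np.array(payload["H"]), Q=np.array(payload["Q"]),
            initial_state=np.array(payload["initial_state"]),
            initial_covariance=np.array(payload["initial_covariance"]),
            state_mean=np.array(payload.get("state_mean"))
            if payload.get("state_mean") is not None else None,
            observation_mean=np.array(payload.get("observation_mean"))
            if payload.get("observation_mean") is not None else None,
        )


@dataclass
class StateSequence:
    """Posterior state trajectory (and optionally covariances)."""

    states: np.ndarray
    covariances: np.ndarray | None = None


def _lstsq_transition(X: np.ndarray, Y: np.ndarray, what: str) -> np.ndarray:
    """Solve min ||Y - X M^T||_F for M, warning on a singular Gram matrix."""
    gram = X.T @ X
    if X.shape[0] < X.shape[1] or np.linalg.matrix_rank(gram) < gram.shape[0]:
        warnings.warn(
            f"singular Gram matrix while estimating {what}; "
            "returning the minimum-norm solution", stacklevel=3,
        )
    M_T, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return M_T.T


def _fit_from_pairs(X_prev, X_next, X_all, Z_all, center: bool) -> KalmanModel:
    if center:
        xm = X_all.mean(axis=0)
        zm = Z_all.mean(axis=0)
        X_prev, X_next = X_prev - xm, X_next - xm
        X_all, Z_all = X_all - xm, Z_all - zm
    else:
        xm = np.zeros(X_all.shape[1])
        zm = np.zeros(Z_all.shape[1])
    A = _lstsq_transition(X_prev, X_next, "A")
    rA = X_next - X_prev @ A.T
    W = rA.T @ rA / max(rA.shape[0] - 1, 1)
    H = _lstsq_transition(X_all, Z_all, "H")
    rH = Z_all - X_all @ H.T
    Q = rH.T @ rH / max(rH.shape[0] - 1, 1)
    return KalmanModel(A=A, W=W, H=H, Q=Q,
                       initial_state=X_all.mean(axis=0) + xm,
                       initial_covariance=W, state_mean=xm, observation_mean=zm)


def fit_kalman(states: np.ndarray, observations: np.ndarray,
               center: bool = False) -> KalmanModel:
    """Least-squares identification of (A, W, H, Q) from aligned data.

    ``A`` minimizes ``sum_t ||x(t) - A x(t-1)||^2`` over consecutive state
    pairs; ``H`` minimizes ``sum_t ||z(t) - H x(t)||^2``.  ``W`` and ``Q``
    are the corresponding residual covariances (divisor T-1).  The decoder
    is initialized at the mean training state with covariance ``W``.

    With ``center=True`` the fits are computed on mean-removed states and
    observations (the means are stored on the model and reapplied during
    decoding) — the usual choice when observations carry a baseline
    offset.
    """
    X = np.atleast_2d(np.asarray(states, dtype=float))
    Z = np.atleast_2d(np.asarray(observations, dtype=float))
    if X.shape[0] != Z.shape[0]:
        raise ValueError("states and observations must have aligned rows")
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need at least state_dim + 1 samples")
    return _fit_from_pairs(X[:-1], X[1:], X, Z, center)


def fit_kalman_pairs(
    state_segments: list[np.ndarray], observation_segments: list[np.ndarray],
    center: bool = False,
) -> KalmanModel:
    """``fit_kalman`` over several contiguous segments.

    Transition pairs never straddle a segment boundary; the observation
    model pools all samples.
    """
    X_prev = np.vstack([seg[:-1] for seg in state_segments if len(seg) > 1])
    X_next = np.vstack([seg[1:] for seg in state_segments if len(seg) > 1])
    X_all = np.vstack([np.atleast_2d(s) for s in state_segments])
    Z_all = np.vstack([np.atleast_2d(z) for z in observation_segments])
    if X_all.shape[0] != Z_all.shape[0]:
        raise ValueError("segments must be aligned")
    return _fit_from_pairs(X_prev, X_next, X_all, Z_all, center)


_JITTER = 1e-9


def _decode_standard(model, Z, x0, P0, keep_cov):
    A, W, H, Q = model.A, model.W, model.H, model.Q
    d = model.state_dim
    T = Z.shape[0]
    states = np.empty((T, d))
    covs = np.empty((T, d, d)) if keep_cov else None
    x, P = x0.copy(), P0.copy()
    eye = np.eye(d)
    for t in range(T):
        x_pred = A @ x
        P_pred = _symmetrize(A @ P @ A.T + W)
        S = _symmetrize(H @ P_pred @ H.T + Q)
        try:
            Sc = cho_factor(S, lower=True)
        except np.linalg.LinAlgError:
            # degenerate prior: regularize the predicted covariance so the
            # innovation covariance becomes invertible
            logger.info("singular innovation covariance at step %d; adding jitter", t)
            scale = max(np.trace(P_pred) / d, 1.0)
            P_pred = _symmetrize(P_pred + _JITTER * scale * eye)
            S = _symmetrize(H @ P_pred @ H.T + Q)
            try:
                Sc = cho_factor(S, lower=True)
            except np.linalg.LinAlgError:
                S = _symmetrize(S + _JITTER * max(np.trace(S) / S.shape[0], 1.0)
                                * np.eye(S.shape[0]))
                Sc = cho_factor(S, lower=True)
        K = P_pred @ cho_solve(Sc, H).T
        x = x_pred + K @ (Z[t] - H @ x_pred)
        P = _symmetrize((eye - K @ H) @ P_pred)
        states[t] = x
        if keep_cov:
            covs[t] = P
    return states, covs


def _decode_information(model, Z, x0, P0, keep_cov):
    """Information-form update; requires invertible Q.  Algebraically equal
    to the standard gain form but O(state_dim^3) per step."""
    A, W, H, Q = model.A, model.W, model.H, model.Q
    d = model.state_dim
    Qc = cho_factor(Q, lower=True)
    HtQi = cho_solve(Qc, H).T          # H^T Q^{-1}, (d, channels)
    M = _symmetrize(HtQi @ H)          # constant information gain
    HtQiZ = Z @ HtQi.T                 # (T, d)
    T = Z.shape[0]
    states = np.empty((T, d))
    covs = np.empty((T, d, d)) if keep_cov else None
    x, P = x0.copy(), P0.copy()
    eye = np.eye(d)
    for t in range(T):
        x_pred = A @ x
        P_pred = _symmetrize(A @ P @ A.T + W)
        try:
            Pc = cho_factor(P_pred, lower=True)
        except np.linalg.LinAlgError:
            scale = max(np.trace(P_pred) / d, 1.0)
            P_pred = _symmetrize(P_pred + _JITTER * scale * eye)
            Pc = cho_factor(P_pred, lower=True)
        Pi = cho_solve(Pc, eye)
        P = _symmetrize(np.linalg.inv(Pi + M))
        x = P @ (Pi @ x_pred + HtQiZ[t])
        states[t] = x
        if keep_cov:
            covs[t] = P
    return states, covs


def kalman_decode(
    model: KalmanModel,
    observations: np.ndarray,
    initial_state: np.ndarray | None = None,
    initial_covariance: np.ndarray | None = None,
    return_covariances: bool = False,
    method: str = "auto",
) -> StateSequence:
    """Run the predict/update recursion over a block of observations.

    ``method`` is ``"standard"`` (textbook gain), ``"information"``
    (requires invertible Q) or ``"auto"``: information form when the
    observation vector is much wider than the state and Q admits a
    Cholesky factorization, standard form otherwise.
    """
    Z = np.atleast_2d(np.asarray(observations, dtype=float))
    if Z.shape[1] != model.n_channels:
        raise ValueError(
            f"observations have {Z.shape[1]} channels; model expects "
            f"{model.n_channels}"
        )
    x0 = (model.initial_state if initial_state is None
          else np.asarray(initial_state, dtype=float)).reshape(model.state_dim)
    P0 = (model.initial_covariance if initial_covariance is None
          else np.asarray(initial_covariance, dtype=float))
    P0 = _symmetrize(np.atleast_2d(P0))
    # run the recursion in mean-removed coordinates when the model was
    # identified with centering (no-op for zero means)
    Z = Z - model.observation_mean
    x0 = x0 - model.state_mean

    if method == "auto":
        method = "standard"
        if model.n_channels >= 2 * model.state_dim:
            try:
                cho_factor(model.Q, lower=True)
                method = "information"
            except np.linalg.LinAlgError:
                pass
    if method == "information":
        states, covs = _decode_information(model, Z, x0, P0, return_covariances)
    elif method == "standard":
        states, covs = _decode_standard(model, Z, x0, P0, return_covariances)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StateSequence(states=states + model.state_mean, covariances=covs)


def decode_segments(
    model: KalmanModel,
    observations: np.ndarray,
    segments: list[tuple[int, int]],
    **kwargs,
) -> list[StateSequence]:
    """Decode each ``[start, stop)`` segment independently.

    The recursion is re-initialized at the model's initial state and
    covariance at every segment start (offline trial-wise decoding).
    """
    Z = np.atleast_2d(np.asarray(observations, dtype=float))
    return [kalman_decode(model, Z[s:e], **kwargs) for s, e in segments]
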