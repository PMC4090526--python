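"""Linear filter decoder: lagged multichannel regression onto velocity.

Each velocity coordinate at time t is a linear combination of the
current and the ``m`` preceding samples of every channel plus a bias:

    v_x(t) = sum_i sum_{j=0..m} a_ij^x z_i(t - j) + a0^x   (same for y)

With 68 channels and a 200 ms history at 50 Hz (m = 10, i.e. 11 sample
points per channel) this is the classic direct decoding baseline for
continuous kinematics.  Weights are fit per coordinate by ordinary
least squares; on rank-deficient designs the minimum-norm solution is
returned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocessing import LaggedDesign, NeuralRecording, build_lagged_design

__all__ = ["LinearFilterModel", "fit_linear_filter", "predict_linear_filter"]


@dataclass
class LinearFilterModel:
    """Weights of the lagged linear regression decoder.

    ``weights`` has shape ``(n*(m+1) + 1, 2)`` — one column per velocity
    coordinate, bias in the last row.
    """

    weights: np.ndarray
    lag_count: int
    channel_count: int
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        expected = self.channel_count * (self.lag_count + 1) + 1
        if self.weights.shape != (expected, 2):
            raise ValueError(
                f"weights must be ({expected}, 2) for n={self.channel_count}, "
                f"m={self.lag_count}; got {self.weights.shape}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def bias(self) -> np.ndarray:
        return self.weights[-1]

    def to_json(self, path=None) -> str:
        payload = {
            "model": "linear_filter",
            "lag_count": self.lag_count,
            "channel_count": self.channel_count,
            "channel_labels": self.channel_labels,
            "weights": self.weights.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LinearFilterModel":
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            payload = json.loads(Path(text).read_text())
        return cls(
            weights=np.array(payload["weights"], dtype=float),
            lag_count=payload["lag_count"],
            channel_count=payload["channel_count"],
            channel_labels=payload.get("channel_labels"),
        )


def fit_linear_filter(
    design: LaggedDesign,
    velocity: np.ndarray,
    row_mask: np.ndarray | None = None,
    ridge: float = 0.0,
) -> LinearFilterModel:
    """Ordinary least squares fit of the lagged design onto 2-D velocity.

    Rows with incomplete lag history are always excluded; an optional
    ``row_mask`` further restricts the training rows (e.g. reach-only).
    ``ridge > 0`` adds L2 shrinkage on the non-bias weights for noisy
    user data; the default is plain regression.
    """
    v = np.atleast_2d(np.asarray(velocity, dtype=float))
    if v.shape[0] != design.X.shape[0] or v.shape[1] != 2:
        raise ValueError("velocity must be (n_rows, 2) aligned with the design")
    rows = design.valid.copy()
    if row_mask is not None:
        rows &= np.asarray(row_mask, dtype=bool)
    X, y = design.X[rows], v[rows]
    if X.shape[0] == 0:
        raise ValueError("no valid training rows")

    col_std = X[:, :-1].std(axis=0) if X.shape[1] > 1 else np.array([])
    if col_std.size and np.any(col_std == 0):
        warnings.warn(
            f"{int(np.count_nonzero(col_std == 0))} constant non-bias design "
            "column(s); fit is collinear", stacklevel=2,
        )
    if ridge > 0:
        n_feat = X.shape[1]
        penalty = np.sqrt(ridge) * np.eye(n_feat)
        penalty[-1, -1] = 0.0  # never shrink the bias
        X = np.vstack([X, penalty])
        y = np.vstack([y, np.zeros((n_feat, 2))])
    weights, *_ = np.linalg.lstsq(X, y, rcond=None)
    return LinearFilterModel(
        weights=weights,
        lag_count=design.lag_count,
        channel_count=design.channel_count,
        channel_labels=design.channel_labels,
    )


def predict_linear_filter(model: LinearFilterModel, recording):
    """Decode velocity from a recording (or channels x samples array).

    Returns ``(velocity, valid)`` where ``velocity`` is (n_samples, 2)
    and ``valid`` flags the samples with complete lag history (the first
    ``m`` samples are computed from zero-padded history and flagged
    invalid).
    """
    if isinstance(recording, NeuralRecording):
        if model.channel_labels is not None:
            if list(recording.channel_labels) != list(model.channel_labels):
                if set(recording.channel_labels) >= set(model.channel_labels):
                    recording = recording.select_channels(model.channel_labels)
                else:
                    raise ValueError("recording channels do not match the model")
        elif recording.n_channels != model.channel_count:
            raise ValueError(
                f"model expects {model.channel_count} channels, "
                f"got {recording.n_channels}"
            )
    design = build_lagged_design(recording, model.lag_count)
    if design.channel_count != model.channel_count:
        raise ValueError(
            f"model expects {model.channel_count} channels, "
            f"got {design.channel_count}"
        )
    return design.X @ model.weights, design.valid
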