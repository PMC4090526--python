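"""Trajectory evaluation: RMSE and task-axis pointing metrics.

Decoded reaches are scored two ways.  Root-mean-squared error gives a
gross accuracy number for position (2-D Euclidean error) or speed
(scalar error).  The four pointing-device accuracy measures score a
single trial against its *task axis*, the straight line from the start
point to the target centre:

- **ODC** (orthogonal direction change): reversals of progress *along*
  the axis — how consistently the trajectory heads toward the target.
- **MDC** (movement direction change): reversals of the *perpendicular*
  deviation — how smooth the path is across the axis.
- **ME** (movement error): mean absolute perpendicular distance from
  the axis.
- **MV** (movement variability): sample standard deviation (n-1
  denominator) of the perpendicular distance.

ODC and MDC are integer counts of sign changes of the per-step
increments of the along/perpendicular coordinate.  Zero increments
inherit the previous nonzero sign (flat segments never add counts) and
leading zero increments are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import project_to_task_axis

__all__ = ["PointingMetrics", "rmse", "pointing_metrics", "summarize_trials"]

METRIC_COLUMNS = ["odc", "mdc", "me", "mv"]


@dataclass
class PointingMetrics:
    """Per-trial pointing accuracy relative to the task axis."""

    odc: int
    mdc: int
    me: float
    mv: float

    def as_dict(self) -> dict:
        return {"odc": self.odc, "mdc": self.mdc, "me": self.me, "mv": self.mv}


def rmse(true_series, decoded_series, valid_mask=None) -> float:
    """Root-mean-squared error between two aligned series.

    For (n, 2) input the per-sample error is the Euclidean norm of the
    difference; for 1-D input it is the absolute difference.  An optional
    boolean mask restricts the average to valid samples.
    """
    a = np.asarray(true_series, dtype=float)
    b = np.asarray(decoded_series, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    err2 = (a - b) ** 2
    if err2.ndim == 2:
        err2 = err2.sum(axis=1)
    if valid_mask is not None:
        err2 = err2[np.asarray(valid_mask, dtype=bool)]
    if err2.size == 0:
        raise ValueError("no valid samples to compare")
    return float(np.sqrt(np.mean(err2)))


def count_sign_changes(increments: np.ndarray) -> int:
    """Count sign reversals in a sequence of increments.

    Zero increments inherit the previous nonzero sign; leading zeros are
    skipped.  Equivalently: the number of sign flips between consecutive
    nonzero increments.
    """
    s = np.sign(np.asarray(increments, dtype=float))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def pointing_metrics(path: np.ndarray, start, target) -> PointingMetrics:
    """Score one decoded trial path against its task axis."""
    path = np.atleast_2d(np.asarray(path, dtype=float))
    if path.shape[0] < 3:
        raise ValueError("need at least 3 points")
    frame = project_to_task_axis(path, start, target)
    odc = count_sign_changes(np.diff(frame.along))
    mdc = count_sign_changes(np.diff(frame.perp))
    me = float(np.mean(np.abs(frame.perp)))
    mv = float(np.std(frame.perp, ddof=1))
    return PointingMetrics(odc=odc, mdc=mdc, me=me, mv=mv)


def summarize_trials(per_trial: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Mean ± standard error of the mean over trials, per metric column.

    Returns a frame indexed by metric with ``mean`` and ``sem``
    (sd / sqrt(n_trials)) columns.
    """
    if len(per_trial) < 2:
        raise ValueError("need at least 2 trials to summarize")
    if columns is None:
        columns = [c for c in per_trial.columns
                   if np.issubdtype(per_trial[c].dtype, np.number)]
    rows = {}
    n = len(per_trial)
    for col in columns:
        vals = per_trial[col].to_numpy(float)
        rows[col] = {"mean": float(np.mean(vals)),
                     "sem": float(np.std(vals, ddof=1) / np.sqrt(n))}
    return pd.DataFrame(rows).T[["mean", "sem"]]
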