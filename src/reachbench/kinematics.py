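"""2-D hand kinematics: containers, velocity integration, speed/direction
decomposition and task-axis projection.

The toolkit models planar (x-y) reaching only.  Velocity is the primary
kinematic signal: it is obtained by integrating a (band-passed)
accelerometer trace once, and position by integrating velocity once more
per trial with a known start point.  A velocity series can be split
losslessly into a nonnegative *speed* and a unit-length *direction*;
the two are recombined by elementwise multiplication.  At samples where
the hand is (nearly) still the direction is undefined, so the last valid
direction is carried forward.

The task axis is the straight line from a movement's start point to the
target centre; trajectories are scored in that frame (signed distance
along the axis and perpendicular to it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "TrajectorySeries",
    "SpeedDirectionSeries",
    "TaskAxisFrame",
    "integrate_acceleration",
    "drop_z",
    "decompose_velocity",
    "compose_velocity",
    "project_to_task_axis",
]

#: Default speed below which the movement direction is considered undefined
#: (length-units per second).
DEFAULT_SPEED_FLOOR = 1e-6

#: Fallback direction used before any sample has exceeded the speed floor.
FALLBACK_DIRECTION = np.array([1.0, 0.0])


def _as_float_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        n_bad = int(np.size(a) - np.count_nonzero(np.isfinite(a)))
        raise ValueError(f"{name} contains {n_bad} non-finite values")
    return a


@dataclass
class TrajectorySeries:
    """Uniformly sampled planar kinematics.

    Parameters
    ----------
    times : (n,) array
        Sample times in seconds on a uniform grid with step ``1/sample_rate``.
    position : (n, 2) array
        x-y position in arbitrary length units.
    velocity : (n, 2) array
        x-y velocity in length-units per second.
    sample_rate : float
        Sampling rate in Hz.
    """

    times: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.position = np.atleast_2d(_as_float_array(self.position, "position"))
        self.velocity = np.atleast_2d(_as_float_array(self.velocity, "velocity"))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = self.times.shape[0]
        if self.position.shape != (n, 2) or self.velocity.shape != (n, 2):
            raise ValueError(
                "position and velocity must be (n, 2) arrays matching times; got "
                f"{self.position.shape} and {self.velocity.shape} for n={n}"
            )
        if n > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniform with step 1/sample_rate")

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    @property
    def speed(self) -> np.ndarray:
        """Euclidean norm of the velocity at each sample."""
        return np.linalg.norm(self.velocity, axis=1)

    @classmethod
    def from_velocity(
        cls,
        velocity: np.ndarray,
        sample_rate: float,
        initial_position=(0.0, 0.0),
        t0: float = 0.0,
    ) -> "TrajectorySeries":
        """Build a series by integrating velocity from a known start point."""
        v = np.atleast_2d(_as_float_array(velocity, "velocity"))
        pos = np.asarray(initial_position, dtype=float) + cumulative_trapezoid(
            v, dx=1.0 / sample_rate, axis=0, initial=0.0
        )
        times = t0 + np.arange(v.shape[0]) / sample_rate
        return cls(times=times, position=pos, velocity=v, sample_rate=sample_rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "pos_x": self.position[:, 0],
                "pos_y": self.position[:, 1],
                "vel_x": self.velocity[:, 0],
                "vel_y": self.velocity[:, 1],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_rate: float | None = None) -> "TrajectorySeries":
        required = ["time_s", "pos_x", "pos_y", "vel_x", "vel_y"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"kinematics table missing columns: {missing}")
        times = frame["time_s"].to_numpy(float)
        if sample_rate is None:
            if len(times) < 2:
                raise ValueError("cannot infer sample_rate from fewer than 2 samples")
            sample_rate = 1.0 / float(np.median(np.diff(times)))
        return cls(
            times=times,
            position=frame[["pos_x", "pos_y"]].to_numpy(float),
            velocity=frame[["vel_x", "vel_y"]].to_numpy(float),
            sample_rate=sample_rate,
        )

    @classmethod
    def read_csv(cls, path, sample_rate: float | None = None) -> "TrajectorySeries":
        return cls.from_frame(pd.read_csv(path), sample_rate=sample_rate)


@dataclass
class SpeedDirectionSeries:
    """Velocity decomposed into nonnegative speed and unit direction."""

    speed: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.speed = _as_float_array(self.speed, "speed")
        self.direction = np.atleast_2d(_as_float_array(self.direction, "direction"))
        if np.any(self.speed < 0):
            raise ValueError("speed must be nonnegative")
        norms = np.linalg.norm(self.direction, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("direction rows must be unit vectors (|norm - 1| <= 1e-6)")

    def compose(self) -> np.ndarray:
        """Recombine into a velocity series (speed × direction)."""
        return compose_velocity(self.speed, self.direction)


@dataclass
class TaskAxisFrame:
    """Trajectory coordinates in the start→target frame.

    ``along`` is the signed distance from the start projected onto the
    start→target line; ``perp`` is the signed perpendicular distance, with
    positive values on the side reached by rotating the axis direction
    +90 degrees (counter-clockwise).
    """

    start: np.ndarray
    target: np.ndarray
    along: np.ndarray
    perp: np.ndarray

    @property
    def axis_length(self) -> float:
        return float(np.linalg.norm(self.target - self.start))

    @property
    def axis_direction(self) -> np.ndarray:
        return (self.target - self.start) / self.axis_length

    def to_points(self) -> np.ndarray:
        """Rotate (along, perp) back into the original x-y plane."""
        u = self.axis_direction
        u_perp = np.array([-u[1], u[0]])
        return self.start + np.outer(self.along, u) + np.outer(self.perp, u_perp)


def integrate_acceleration(accel: np.ndarray, sample_rate: float) -> np.ndarray:
    """Cumulative trapezoidal integral of an acceleration series.

    Accepts 1-D, (n, 2) or (n, 3) input (time along the first axis) and
    returns the velocity with the same shape, starting from zero velocity.
    """
    a = _as_float_array(accel, "accel")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    return cumulative_trapezoid(a, dx=1.0 / sample_rate, axis=0, initial=0.0)


def drop_z(series: np.ndarray) -> np.ndarray:
    """Reduce an (n, 3) x-y-z series to the x-y plane (with a warning)."""
    s = np.atleast_2d(np.asarray(series, dtype=float))
    if s.shape[1] == 2:
        return s
    if s.shape[1] == 3:
        warnings.warn("dropping z component; only the x-y plane is modeled", stacklevel=2)
        return s[:, :2]
    raise ValueError(f"expected 2 or 3 columns, got {s.shape[1]}")


def decompose_velocity(
    velocity: np.ndarray, speed_floor: float = DEFAULT_SPEED_FLOOR
) -> SpeedDirectionSeries:
    """Split a 2-D velocity series into speed and unit direction.

    Where the speed does not exceed ``speed_floor`` the direction is
    undefined; the last valid direction is carried forward (fallback
    ``(1, 0)`` if no sample has been valid yet).
    """
    v = np.atleast_2d(_as_float_array(velocity, "velocity"))
    if v.shape[1] != 2:
        raise ValueError("velocity must have two columns (x, y)")
    speed = np.linalg.norm(v, axis=1)
    valid = speed > speed_floor

    direction = np.tile(FALLBACK_DIRECTION, (v.shape[0], 1))
    direction[valid] = v[valid] / speed[valid, None]
    # carry the last valid direction forward over invalid runs
    idx = np.where(valid, np.arange(v.shape[0]), -1)
    idx = np.maximum.accumulate(idx)
    filled = idx >= 0
    direction[filled] = direction[idx[filled]]
    return SpeedDirectionSeries(speed=speed, direction=direction)


def compose_velocity(speed: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Elementwise speed × unit-direction product.

    Rejects direction rows whose norm deviates from 1 by more than 1e-6.
    """
    s = _as_float_array(speed, "speed")
    d = np.atleast_2d(_as_float_array(direction, "direction"))
    if np.any(s < 0):
        raise ValueError("speed must be nonnegative")
    norms = np.linalg.norm(d, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        worst = float(np.max(np.abs(norms - 1.0)))
        raise ValueError(f"direction rows must be unit vectors (worst |norm-1| = {worst:.2e})")
    return s[:, None] * d


def project_to_task_axis(points: np.ndarray, start, target) -> TaskAxisFrame:
    """Project points onto the start→target task axis.

    Returns signed along-axis and perpendicular coordinates.  The
    perpendicular unit vector is the +90° (counter-clockwise) rotation of
    the axis direction, so the transform is a rigid rotation+translation
    and preserves distances from the start point.
    """
    p = np.atleast_2d(_as_float_array(points, "points"))
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    axis = target - start
    length = float(np.linalg.norm(axis))
    if length <= 0:
        raise ValueError("start and target must not coincide")
    u = axis / length
    u_perp = np.array([-u[1], u[0]])
    rel = p - start
    return TaskAxisFrame(start=start, target=target, along=rel @ u, perp=rel @ u_perp)
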