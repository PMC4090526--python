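"""Neural-signal conditioning: band-pass filtering, downsampling,
epoching, channel subsetting, lagged design matrices and reach/rest
state labeling.

The chain mirrors a standard offline kinematic-decoding pipeline for
band-limited sensor data: zero-phase Butterworth band-pass (0.5-8 Hz for
the neural channels, 0.2-5 Hz for an accelerometer), downsampling to
50 Hz, epoching around target onsets, and construction of a lagged
regression design (current sample plus ``m`` preceding samples per
channel, plus a bias column).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "NeuralRecording",
    "EpochSet",
    "LaggedDesign",
    "bandpass",
    "downsample",
    "epoch",
    "build_lagged_design",
    "label_states",
]


@dataclass
class NeuralRecording:
    """Multichannel neural time series (channels x samples)."""

    data: np.ndarray
    sample_rate: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def select_channels(self, labels) -> "NeuralRecording":
        """Return the sub-recording holding ``labels``, in the given order."""
        index = {lab: i for i, lab in enumerate(self.channel_labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"unknown channels: {missing}")
        rows = [index[lab] for lab in labels]
        return NeuralRecording(self.data[rows], self.sample_rate, list(labels))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data.T, columns=self.channel_labels)
        frame.insert(0, "time_s", self.times)
        return frame

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, sample_rate: float | None = None) -> "NeuralRecording":
        frame = pd.read_csv(path)
        if "time_s" not in frame.columns:
            raise ValueError("neural CSV must have a time_s first column")
        times = frame["time_s"].to_numpy(float)
        if sample_rate is None:
            if len(times) < 2:
                raise ValueError("cannot infer sample_rate from fewer than 2 samples")
            sample_rate = 1.0 / float(np.median(np.diff(times)))
        labels = [c for c in frame.columns if c != "time_s"]
        return cls(frame[labels].to_numpy(float).T, sample_rate, labels)

    def write_binary(self, path) -> None:
        """Flat float64 array file with a JSON sidecar (``<path>.json``)."""
        path = Path(path)
        self.data.astype(np.float64).tofile(path)
        sidecar = {
            "sample_rate": self.sample_rate,
            "channels": self.channel_labels,
            "n_samples": self.n_samples,
            "dtype": "float64",
            "order": "channels_x_samples",
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read_binary(cls, path) -> "NeuralRecording":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        data = np.fromfile(path, dtype=np.float64).reshape(
            len(meta["channels"]), meta["n_samples"]
        )
        return cls(data, meta["sample_rate"], list(meta["channels"]))


@dataclass
class EpochSet:
    """Trials x channels x samples array cut around event onsets."""

    epochs: np.ndarray
    window: tuple[float, float]
    trial_labels: list
    state_mask: np.ndarray | None = None
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2] if self.epochs.ndim == 3 else 0


@dataclass
class LaggedDesign:
    """Design matrix of lagged channel values plus a bias column.

    Row ``t`` holds ``z_i(t - j)`` for every channel ``i`` and lag
    ``j = 0..m`` (column order: channel-major, lag-minor), then a constant
    1.  The first ``m`` rows have incomplete history and are flagged
    invalid; they are zero-filled, never used for fitting.
    """

    X: np.ndarray
    valid: np.ndarray
    lag_count: int
    channel_count: int
    channel_labels: list[str] | None = None

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def _apply_bandpass(data: np.ndarray, low_hz: float, high_hz: float,
                    sample_rate: float, order: int, axis: int) -> np.ndarray:
    nyq = sample_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got [{low_hz}, {high_hz}]"
        )
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass",
                           fs=sample_rate, output="sos")
    return sp_signal.sosfiltfilt(sos, data, axis=axis)


def bandpass(recording, low_hz: float, high_hz: float,
             sample_rate: float | None = None, order: int = 4):
    """Zero-phase Butterworth band-pass.

    ``recording`` may be a :class:`NeuralRecording` (filtered along time,
    axis 1) or a plain array with time along the first axis, in which case
    ``sample_rate`` is required.  The filter is applied forward and
    backward (``sosfiltfilt``), doubling the effective order and removing
    phase distortion.
    """
    if isinstance(recording, NeuralRecording):
        out = _apply_bandpass(recording.data, low_hz, high_hz,
                              recording.sample_rate, order, axis=1)
        return NeuralRecording(out, recording.sample_rate, list(recording.channel_labels))
    if sample_rate is None:
        raise ValueError("sample_rate required for array input")
    return _apply_bandpass(np.asarray(recording, dtype=float), low_hz, high_hz,
                           sample_rate, order, axis=0)


def downsample(recording, target_rate: float, sample_rate: float | None = None):
    """Reduce the sampling rate of an already low-passed signal.

    With an integer decimation ratio the signal is sliced directly (the
    preceding band-pass is assumed to prevent aliasing); otherwise
    polyphase resampling is used for any rational ratio.
    """
    if isinstance(recording, NeuralRecording):
        data, rate, axis = recording.data, recording.sample_rate, 1
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for array input")
        data, rate, axis = np.asarray(recording, dtype=float), sample_rate, 0
    if target_rate >= rate:
        raise ValueError("target_rate must be below the current sample rate")
    ratio = rate / target_rate
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        out = data[:, ::q] if axis == 1 else data[::q]
    else:
        frac = Fraction(target_rate / rate).limit_denominator(10_000)
        out = sp_signal.resample_poly(data, frac.numerator, frac.denominator, axis=axis)
    if isinstance(recording, NeuralRecording):
        return NeuralRecording(out, target_rate, list(recording.channel_labels))
    return out


def epoch(recording: NeuralRecording, onsets, t_min: float, t_max: float,
          trial_labels=None) -> EpochSet:
    """Cut fixed-length windows around event onsets.

    The window runs from ``t_min`` (negative: before onset) to ``t_max``
    seconds relative to each onset and contains
    ``round((t_max - t_min) * rate) + 1`` samples.  Onsets whose window
    falls outside the recording are dropped with a warning; the drop count
    is reported on the returned :class:`EpochSet`.
    """
    if not t_min < 0 < t_max:
        raise ValueError("window must satisfy t_min < 0 < t_max")
    onsets = np.asarray(list(onsets), dtype=float)
    rate = recording.sample_rate
    n_samp = int(round((t_max - t_min) * rate)) + 1
    if trial_labels is None:
        trial_labels = [None] * len(onsets)

    kept, labels = [], []
    n_dropped = 0
    for onset, label in zip(onsets, trial_labels):
        start = int(round((onset + t_min) * rate))
        if start < 0 or start + n_samp > recording.n_samples:
            n_dropped += 1
            continue
        kept.append(recording.data[:, start:start + n_samp])
        labels.append(label)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} out-of-range epoch(s)", stacklevel=2)
    epochs = (np.stack(kept, axis=0) if kept
              else np.empty((0, recording.n_channels, n_samp)))
    return EpochSet(epochs=epochs, window=(t_min, t_max), trial_labels=labels,
                    n_dropped=n_dropped)


def build_lagged_design(recording, m: int, channel_labels=None) -> LaggedDesign:
    """Lagged design matrix: ``n_channels * (m + 1)`` feature columns + bias.

    Accepts a :class:`NeuralRecording` or a channels x samples array.
    """
    if isinstance(recording, NeuralRecording):
        data = recording.data
        channel_labels = list(recording.channel_labels)
    else:
        data = np.atleast_2d(np.asarray(recording, dtype=float))
    if m < 0:
        raise ValueError("lag count m must be >= 0")
    n, T = data.shape
    if T <= m:
        raise ValueError(f"need more than m={m} samples, got {T}")
    X = np.zeros((T, n * (m + 1) + 1))
    X[:, -1] = 1.0
    for j in range(m + 1):
        # columns for lag j of every channel: i*(m+1) + j
        X[j:, j:n * (m + 1):m + 1] = data[:, :T - j].T
    valid = np.arange(T) >= m
    return LaggedDesign(X=X, valid=valid, lag_count=m, channel_count=n,
                        channel_labels=channel_labels)


def label_states(speed: np.ndarray, sample_rate: float,
                 threshold_frac: float = 0.05, min_duration_s: float = 0.1,
                 peak_speed: float | None = None) -> np.ndarray:
    """Label each sample reach (True) or rest (False) from the hand speed.

    A sample is *rest* when it belongs to a contiguous run of at least
    ``min_duration_s`` during which the speed stays below
    ``threshold_frac`` x the session peak speed; everything else is
    *reach*.  Requiring a minimum rest duration acts as hysteresis: brief
    dips below threshold inside a movement stay labeled reach.
    """
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be nonnegative")
    peak = float(np.max(speed)) if peak_speed is None else float(peak_speed)
    if peak == 0.0:
        return np.zeros(speed.shape[0], dtype=bool)
    below = speed < threshold_frac * peak
    min_run = max(1, int(round(min_duration_s * sample_rate)))

    reach = np.ones(speed.shape[0], dtype=bool)
    # scan runs of below-threshold samples
    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [below.shape[0]]])
    for s, e in zip(starts, ends):
        if below[s] and (e - s) >= min_run:
            reach[s:e] = False
    return reach
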