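"""Seeded generator of synthetic center-out reaching sessions.

Emulates the structure of a center-out pointing experiment: four corner
targets, thirty trials per target in pseudorandom balanced order, each
trial an out-and-back movement (total duration ~0.93 s, jittered across
trials) followed by a rest interval of 4 s, sampled at 50 Hz.  Reaches
follow the minimum-jerk quintic, the canonical point-to-point model
whose speed profile is the bell shape the hybrid decoder targets.

Surrogate neural signals (68 channels by default) encode the kinematics
with per-channel lags: each channel mixes a linear velocity term with,
on a subset of channels, a sigmoidal (nonlinear) speed-tuning term,
plus band-limited (0.5-8 Hz) Gaussian noise.  The nonlinear speed term
is what gives the MLP speed read-out a learnable edge over purely
linear decoders; the linear term keeps the linear and Kalman decoders
viable.  All randomness flows through one seeded generator, so equal
seeds give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kinematics import TrajectorySeries
from .preprocessing import NeuralRecording, bandpass

__all__ = [
    "SyntheticConfig",
    "Session",
    "minimum_jerk_profile",
    "gen_minimum_jerk_reach",
    "gen_session",
    "encode_neural",
]

TARGET_LABELS = ("upper_left", "upper_right", "bottom_left", "bottom_right")


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic session.

    Kinematic units are centimeters (targets sit at the corners of a
    +-``corner_offset`` cm square) and seconds.
    """

    n_targets: int = 4
    trials_per_target: int = 30
    movement_duration_s: float = 0.93     # total out-and-back time
    duration_jitter_sd: float = 0.1
    duration_jitter_max: float = 0.3
    movement_window_s: float = 1.3        # slot time reserved for movement
    inter_trial_s: float = 4.0
    sample_rate: float = 50.0
    n_channels: int = 68
    corner_offset: float = 10.0
    # encoding: directional (linear velocity) information is deliberately
    # weak relative to the movement-intensity (nonlinear speed) term,
    # reflecting the weak sensor-level directional tuning and strong
    # movement-evoked amplitude modulation of noninvasive recordings
    linear_gain_scale: float = 0.25       # velocity-term amplitude (unit-free)
    nonlinear_gain_scale: float = 1.5     # sigmoid speed-term amplitude
    nonlinear_fraction: float = 0.35      # channels carrying the sigmoid speed term
    nonlinear_threshold_frac: float = 0.3  # sigmoid threshold, fraction of peak speed
    nonlinear_width_frac: float = 0.15     # sigmoid width, fraction of peak speed
    lag_max_samples: int = 5
    noise_sd: float = 0.5
    outbound_only: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_targets, self.trials_per_target, self.n_channels) <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.movement_duration_s < self.inter_trial_s:
            raise ValueError("movement duration must be positive and below the rest interval")
        if self.movement_duration_s + self.duration_jitter_max > self.movement_window_s:
            raise ValueError("movement window too short for the jittered duration")
        if self.n_targets > len(TARGET_LABELS):
            raise ValueError(f"at most {len(TARGET_LABELS)} targets supported")

    @property
    def n_trials(self) -> int:
        return self.n_targets * self.trials_per_target

    @property
    def trial_period_s(self) -> float:
        """One trial slot: rest interval followed by the movement window."""
        return self.inter_trial_s + self.movement_window_s

    @property
    def target_positions(self) -> dict[str, np.ndarray]:
        c = self.corner_offset
        coords = {
            "upper_left": (-c, c), "upper_right": (c, c),
            "bottom_left": (-c, -c), "bottom_right": (c, -c),
        }
        return {lab: np.array(coords[lab], dtype=float)
                for lab in TARGET_LABELS[: self.n_targets]}

    @property
    def nominal_peak_speed(self) -> float:
        """Peak speed of an unjittered one-way reach (cm/s)."""
        dist = float(np.hypot(self.corner_offset, self.corner_offset))
        one_way = self.movement_duration_s / 2.0
        return 1.875 * dist / one_way


@dataclass
class Session:
    """One generated session: kinematics, events and ground truth."""

    kinematics: TrajectorySeries
    events: pd.DataFrame       # onset_s, target_label per trial
    trials: pd.DataFrame       # sample-index bookkeeping per trial
    reach_mask: np.ndarray     # True on ground-truth movement samples
    config: SyntheticConfig
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.events)

    def trial_slices(self, segment: str = "slot") -> list[tuple[int, int]]:
        """Per-trial ``[start, stop)`` sample ranges.

        ``segment``: ``"slot"`` (full trial period), ``"movement"``
        (out-and-back) or ``"outbound"`` (center-to-target only).
        """
        out = []
        for row in self.trials.itertuples():
            if segment == "slot":
                out.append((row.slot_start_idx, row.slot_end_idx))
            elif segment == "movement":
                out.append((row.onset_idx, row.move_end_idx))
            elif segment == "outbound":
                out.append((row.onset_idx, row.outbound_end_idx))
            else:
                raise ValueError(f"unknown segment {segment!r}")
        return out


def minimum_jerk_profile(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk path fraction and its derivative w.r.t. tau in [0, 1].

    s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5; s'(tau) peaks at 1.875 at
    tau = 1/2.
    """
    tau = np.asarray(tau, dtype=float)
    s = tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)
    ds = 30.0 * tau ** 2 * (1.0 - tau) ** 2
    return s, ds


def gen_minimum_jerk_reach(
    start, target, duration: float, sample_rate: float, t0: float = 0.0
) -> TrajectorySeries:
    """One point-to-point minimum-jerk reach sampled on a uniform grid."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    n = int(round(duration * sample_rate)) + 1
    times = np.arange(n) / sample_rate
    tau = np.clip(times / duration, 0.0, 1.0)
    s, ds = minimum_jerk_profile(tau)
    disp = target - start
    position = start + np.outer(s, disp)
    velocity = np.outer(ds / duration, disp)
    return TrajectorySeries(times=t0 + times, position=position,
                            velocity=velocity, sample_rate=sample_rate)


def _draw_duration(cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    jitter = rng.normal(0.0, cfg.duration_jitter_sd)
    jitter = float(np.clip(jitter, -cfg.duration_jitter_max, cfg.duration_jitter_max))
    return cfg.movement_duration_s + jitter


def gen_session(cfg: SyntheticConfig, seed: int | None = None) -> Session:
    """Generate one center-out session of kinematics and event times.

    Each trial slot is a rest interval followed by the movement window;
    target onset sits at the start of the movement window.  The target
    order is an exact-balance pseudorandom permutation.  The ground-truth
    reach mask marks the movement interval of every trial.
    """
    if seed is None:
        seed = cfg.rng_seed
    rng = np.random.default_rng(seed)
    rate = cfg.sample_rate
    labels = list(cfg.target_positions)
    order = np.repeat(np.arange(cfg.n_targets), cfg.trials_per_target)
    order = order[rng.permutation(order.size)]

    slot_n = int(round(cfg.trial_period_s * rate))
    rest_n = int(round(cfg.inter_trial_s * rate))
    n_total = cfg.n_trials * slot_n

    position = np.zeros((n_total, 2))
    velocity = np.zeros((n_total, 2))
    reach_mask = np.zeros(n_total, dtype=bool)
    center = np.zeros(2)

    ev_rows, tr_rows = [], []
    for k, tgt_idx in enumerate(order):
        label = labels[tgt_idx]
        target = cfg.target_positions[label]
        slot_start = k * slot_n
        onset_idx = slot_start + rest_n
        onset_t = onset_idx / rate
        total_dur = _draw_duration(cfg, rng)
        one_way = total_dur if cfg.outbound_only else total_dur / 2.0

        phases = [(0.0, center, target)]
        if not cfg.outbound_only:
            phases.append((one_way, target, center))
        move_dur = one_way if cfg.outbound_only else total_dur
        # movement samples are exactly those with 0 <= t_rel <= move_dur,
        # so the movement slice coincides with the ground-truth reach mask
        move_end = min(onset_idx + int(np.floor(move_dur * rate)) + 1, n_total)
        t_rel = np.arange(onset_idx, move_end) / rate - onset_t
        pos_seg = np.tile(center, (t_rel.size, 1))
        vel_seg = np.zeros((t_rel.size, 2))
        for phase_t0, p_from, p_to in phases:
            tau = (t_rel - phase_t0) / one_way
            in_phase = (tau >= 0) & (tau <= 1)
            s, ds = minimum_jerk_profile(np.clip(tau, 0.0, 1.0))
            disp = p_to - p_from
            pos_seg[in_phase] = p_from + np.outer(s[in_phase], disp)
            vel_seg[in_phase] = np.outer(ds[in_phase] / one_way, disp)
        position[onset_idx:move_end] = pos_seg
        velocity[onset_idx:move_end] = vel_seg
        if cfg.outbound_only:
            position[move_end:(k + 1) * slot_n] = target
        reach_mask[onset_idx:move_end] = True

        outbound_end = onset_idx + int(round(one_way * rate)) + 1
        ev_rows.append({"trial": k, "onset_s": onset_t, "target_label": label,
                        "target_x": target[0], "target_y": target[1]})
        tr_rows.append({
            "trial": k, "target_label": label,
            "slot_start_idx": slot_start, "slot_end_idx": slot_start + slot_n,
            "onset_idx": onset_idx, "move_end_idx": move_end,
            "outbound_end_idx": min(outbound_end, move_end),
            "movement_duration_s": total_dur,
        })

    times = np.arange(n_total) / rate
    kin = TrajectorySeries(times=times, position=position, velocity=velocity,
                           sample_rate=rate)
    return Session(kinematics=kin, events=pd.DataFrame(ev_rows),
                   trials=pd.DataFrame(tr_rows), reach_mask=reach_mask,
                   config=cfg, seed=seed)


def encode_neural(
    session_or_kinematics, cfg: SyntheticConfig, seed: int | None = None
) -> NeuralRecording:
    """Encode kinematics into surrogate band-limited multichannel signals.

    Channel i mixes a lagged linear velocity term and (on a random subset
    of channels) a lagged sigmoidal speed-tuning term:

        z_i(t) = g_i . v(t - l_i) + h_i sigma((r(t - l_i) - theta) / kappa) + n_i(t)

    with n_i white Gaussian noise band-pass filtered to 0.5-8 Hz.  Gains
    are scaled by the nominal peak speed so clean channel amplitudes are
    O(1) regardless of kinematic units.
    """
    kin = (session_or_kinematics.kinematics
           if isinstance(session_or_kinematics, Session) else session_or_kinematics)
    if seed is None:
        seed = cfg.rng_seed + 1
    if abs(kin.sample_rate - cfg.sample_rate) > 1e-9:
        raise ValueError("kinematics must be sampled at the configured rate")
    if cfg.lag_max_samples >= kin.n_samples:
        raise ValueError("channel lag exceeds the series length")
    rng = np.random.default_rng(seed)
    v = kin.velocity
    speed = kin.speed
    n_samp = v.shape[0]
    v_ref = cfg.nominal_peak_speed
    theta = cfg.nonlinear_threshold_frac * v_ref
    kappa = cfg.nonlinear_width_frac * v_ref

    lags = rng.integers(0, cfg.lag_max_samples + 1, size=cfg.n_channels)
    gains = (rng.normal(0.0, 1.0, size=(cfg.n_channels, 2))
             * cfg.linear_gain_scale / v_ref)
    n_nonlin = int(round(cfg.nonlinear_fraction * cfg.n_channels))
    nonlin_channels = rng.choice(cfg.n_channels, size=n_nonlin, replace=False)
    h = np.zeros(cfg.n_channels)
    h[nonlin_channels] = (rng.uniform(0.5, 1.5, size=n_nonlin)
                          * rng.choice([-1.0, 1.0], size=n_nonlin)
                          * cfg.nonlinear_gain_scale)

    data = np.empty((cfg.n_channels, n_samp))
    for i in range(cfg.n_channels):
        lag = int(lags[i])
        v_lag = np.vstack([np.repeat(v[:1], lag, axis=0), v[: n_samp - lag]])
        s_lag = np.concatenate([np.repeat(speed[:1], lag), speed[: n_samp - lag]])
        clean = v_lag @ gains[i]
        if h[i] != 0.0:
            clean = clean + h[i] / (1.0 + np.exp(-(s_lag - theta) / kappa))
        data[i] = clean
    if cfg.noise_sd > 0:
        noise = rng.normal(0.0, cfg.noise_sd, size=data.shape)
        noise = bandpass(noise.T, 0.5, 8.0, sample_rate=cfg.sample_rate).T
        data = data + noise
    return NeuralRecording(data=data, sample_rate=cfg.sample_rate)


def write_fixture_dataset(out_dir, cfg: SyntheticConfig | None = None,
                          seed: int = 1234) -> dict:
    """Write a small deterministic dataset (CSV) for tests and demos."""
    from pathlib import Path

    if cfg is None:
        cfg = SyntheticConfig(trials_per_target=2, n_channels=8)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session = gen_session(cfg, seed)
    rec = encode_neural(session, cfg, seed + 1)
    session.kinematics.write_csv(out / "kinematics.csv")
    rec.write_csv(out / "neural.csv")
    session.events.to_csv(out / "events.csv", index=False)
    session.trials.to_csv(out / "trials.csv", index=False)
    manifest = {"seed": seed, "config": asdict(cfg),
                "files": ["kinematics.csv", "neural.csv", "events.csv", "trials.csv"]}
    import json
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
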