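"""Generate a synthetic center-out session and inspect its structure.

Builds the default 120-trial session (4 corner targets, 30 trials each,
out-and-back minimum-jerk reaches at 50 Hz) plus the surrogate
68-channel neural encoding, and prints the bookkeeping a decoding study
needs: trial counts, movement durations and the reach/rest split.
"""

import numpy as np

from reachbench import SyntheticConfig, encode_neural, gen_session

cfg = SyntheticConfig()
session = gen_session(cfg, seed=0)
recording = encode_neural(session, cfg, seed=1)

counts = {k: int(v) for k, v in session.events.target_label.value_counts().items()}
print(f"trials: {session.n_trials} ({counts})")
print(f"samples: {session.kinematics.n_samples} at {cfg.sample_rate:g} Hz "
      f"({session.kinematics.n_samples / cfg.sample_rate:.0f} s)")
durations = session.trials.movement_duration_s
print(f"movement duration: {durations.mean():.3f} +- {durations.std():.3f} s "
      "(out-and-back, jittered around 0.93 s)")
print(f"reach fraction: {session.reach_mask.mean():.1%} of samples")
print(f"neural: {recording.n_channels} channels, "
      f"per-channel sd {recording.data.std(axis=1).mean():.2f} "
      "(velocity + nonlinear speed terms + band-limited noise)")
print(f"peak hand speed: {session.kinematics.speed.max():.1f} cm/s")
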