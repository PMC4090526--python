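# Methods

## Scope and data model

The toolkit decodes planar (x–y) hand kinematics from band-limited
multichannel neural time series sampled on a common 50 Hz grid.  Kinematics
live in a `TrajectorySeries` (uniform times, position, velocity); velocity
may be obtained from a 3-axis accelerometer by band-passing (0.2–5 Hz) and
one cumulative-trapezoid integration, with the z axis dropped.  Position is
always recovered downstream by integrating decoded velocity per trial from
the known trial start point — decoders never estimate position directly.

Speed/direction decomposition is exact where the hand moves: `speed` is the
Euclidean norm, `direction = velocity / speed`.  Below a configurable speed
floor (default 1e−6 units/s) the direction is undefined; at *decode* time
the last valid direction is carried forward (fallback (1, 0)).

## Signal conditioning

Band-pass filtering uses a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), i.e. zero-phase with doubled effective order — appropriate
for an offline study; a causal variant is deliberately out of scope.
Passband gain is within ~1% of unity mid-band, which bounds how exactly
"filter then downsample" can match "downsample" even for band-limited
input.  Downsampling slices directly when the rate ratio is an integer (the
0.5–8 Hz band-pass already prevents aliasing at 50 Hz) and uses polyphase
resampling otherwise.  Epochs of (−1, 2) s around target onset contain
round(3·rate)+1 = 151 samples at 50 Hz; out-of-range onsets are dropped
with a warning and counted.

Lagged design matrices hold the current sample plus `m` preceding samples
per channel (column order channel-major, lag-minor) and a bias column; the
first `m` rows are flagged invalid and excluded from fitting rather than
zero-padded, avoiding edge bias.

Reach/rest labeling is a speed-threshold rule with hysteresis: a sample is
rest when it belongs to a run of at least `min_duration_s` (default 0.1 s)
below `threshold_frac` (default 0.05) of the session peak speed.  On an
isolated minimum-jerk reach this recovers ~88% of the nominal movement
interval — the analytic ceiling, since the quintic profile sits below 5% of
peak outside τ ∈ [0.059, 0.941].

## Decoder identification

The linear filter is plain OLS per velocity coordinate (minimum-norm on
rank deficiency; optional ridge for user data, off by default).

Kalman models are identified by least squares: A from consecutive state
pairs, H from aligned state/observation rows, W and Q as residual
covariances with 1/(T−1) normalization.  Two identification details matter
in practice and are options on `fit_kalman` / defaults in the pipeline:

- **Mean centering** (`center=True` in the pipeline): states and
  observations are mean-removed before fitting and the means stored on the
  model and reapplied at decode.  The surrogate channels carry a baseline
  offset (the sigmoid speed term is nonzero at rest), which an uncentered
  fit forces the state to explain.  The uncentered fit remains the
  documented default of the plain function, whose contract is the raw
  least-squares problem.
- **Transition pairs never straddle segment boundaries**
  (`fit_kalman_pairs`), so concatenated training trials do not inject
  spurious jumps into A and W.

Decoding is the standard predict/update recursion, re-initialized at the
mean training state with covariance W at every trial segment (offline
trial-wise decoding; continuous mode available by passing one segment).
When the observation vector is much wider than the state and Q admits a
Cholesky factorization, the update runs in information form with a
precomputed Q⁻¹ — algebraically identical to the textbook gain (verified
numerically in the tests) but O(d³) instead of O(c³) per step.  Degenerate
innovation covariances are handled by adding 1e−9-scale jitter to the
predicted state covariance, which preserves the exact-observation limit
(Q = 0 ⇒ posterior = H⁻¹z).

## Hybrid decoder choices

The 5-dim state is [r(t), r(t−1), r(t−2), d_x, d_y] built from training
velocity; the two lagged speed columns are edge-replicated at the start.

**Direction state at rest.**  In training states the direction components
are set to zero where speed does not exceed the floor.  With carried-forward
directions instead (available as `direction_at_rest="carry"`), the ~80% rest
samples pair a stale nonzero direction with direction-free observations;
on noiseless synthetic kinematics this attenuates the direction columns of
H several-fold and drives the estimated direction process noise to nearly
zero, leaving the decoded direction unable to track movement (mean cosine
to the true direction ~0.4, including complete failure to follow the
mid-trial reversal of out-and-back reaches).  The null-direction convention
treats "movement direction" as absent while the hand is still; the system
model then learns that direction collapses between movements and re-forms
at onset, and decode-time normalization (which still carries forward over
degenerate posteriors) supplies a unit vector at every sample.

**MLP speed read-out.**  3 → 18 (tanh) → 1 (logistic sigmoid).  Inputs and
targets are divided by `speed_scale` = max training speed, so the output
covers (0, speed_scale); posterior speed states above the ceiling saturate
and are logged.  Training minimizes half-MSE with Møller's scaled conjugate
gradient: σ = 1e−4, λ₀ = 1e−6, at most 500 iterations, gradient-norm
tolerance 1e−6, weights initialized uniform(−0.5, 0.5)/√fan-in from a
recorded seed.  One deviation from Møller's published pseudocode: the
trust parameter λ is adapted multiplicatively (×4 on a failed step, ×0.5 on
a very good one, as in the widely used netlab implementation).  The
additive update resets its reference λ̄ on every failure, so after one bad
conjugate direction the step size stops shrinking and the optimizer can
loop without progress — we observed exactly this stall on reach-only
training sets.  Accepted-step losses are recorded and are non-increasing by
construction.

**What the MLP is trained on.**  By default the MLP inputs are the Kalman
*posterior* speed states obtained by decoding the training observations,
with the true current speed as target (`mlp_inputs="posterior"`); pure
teacher forcing on ground-truth states is available (`"true"`).  Trained on
true states the network's optimal solution is the identity map (the target
r(t) is its own first input), which makes the read-out equivalent to the
no-MLP ablation; trained on posteriors it learns to denoise and recalibrate
the filtered states, which is the function it must perform at decode time.

**Read-out independence.**  The MLP receives only the three speed states
(input width 3, asserted), respecting the speed/direction independence
assumption.  The decoded velocity is MLP-speed × unit direction; the full
and ablation variants share the identical posterior sequence and differ
only in the speed read-out (the ablation clips negative r(t) at zero, since
a speed is composed with a unit direction).

## Synthetic study conditions

The generator emulates a center-out session: 4 corner targets at
(±10, ±10) cm, 30 trials per target in an exactly balanced pseudorandom
order, 50 Hz.  Each trial slot is 4 s of rest followed by a 1.3 s movement
window holding an out-and-back pair of minimum-jerk reaches with total
duration 0.93 s jittered by N(0, 0.1²) truncated to ±0.3 s (the window is
sized to contain the maximum).  The minimum-jerk quintic is used because it
is the standard point-to-point model and gives closed-form oracles (peak
speed 1.875·D/T at the midpoint).

Channel i of the surrogate recording is

    z_i(t) = g_i·v(t−ℓ_i) + h_i·σ((r(t−ℓ_i) − θ)/κ) + n_i(t)

with per-channel lags ℓ_i ∈ {0..5} samples, linear gains g_i ~ N(0, s²)/v_ref
(s = 0.25), a sigmoidal speed term (gain magnitude 0.75–2.25, random sign)
on 35% of channels with threshold θ = 0.3·v_ref and width κ = 0.15·v_ref,
and white Gaussian noise (sd 0.5) band-passed to 0.5–8 Hz.  v_ref is the
nominal one-way peak speed, so clean channel amplitudes are O(1) in any
kinematic units.

The gain choice encodes the study condition the hybrid design targets:
weak sensor-level directional (linear velocity) tuning combined with strong
but nonlinear movement-intensity modulation, as is characteristic of
noninvasive recordings.  This matters for interpretation: when the linear
gains are made strong, the lagged OLS filter becomes essentially the
optimal read-out of its own generative class and no state-space decoder
beats it on position — the decoder ranking is a property of the encoding
regime, not of the algorithms alone.

What the generator does **not** emulate: spatially correlated background
activity, nonstationary gains, measurement noise on the kinematics,
artifacts, or across-subject variability.  Passing benchmarks here
therefore demonstrate correctness and the intended qualitative ordering
under the stated encoding, not performance on real recordings.

## Benchmark protocol

Trial-wise stratified k-fold cross-validation (default k = 5, seeded);
every trial is decoded exactly once as a held-out trial.  Two regimes:
`reach_rest` trains and scores on full trial periods; `reach_only` excludes
rest samples from both training and evaluation (training segments are
verified against the ground-truth mask).  Decoding re-initializes per
evaluation segment.  Position RMSE integrates decoded velocity from the
true segment-start position; pointing metrics are computed on the outbound
reach (configurable).  Decoders are compared by paired t-tests on per-trial
errors, without multiple-testing correction (noted in the report
provenance).  The ten-session acceptance study uses a single stratified
75/25 split per session in the reach+rest regime to keep the runtime to a
few minutes.

## Known limitations

- In the reach-only regime the hybrid's direction posterior must converge
  within a ~0.9 s movement after each re-initialization, and its position
  RMSE can trail the linear filter there even while its speed RMSE is
  competitive; the reach+rest regime gives the direction state the
  inter-trial interval to settle.
- The MLP's sigmoid output is strictly positive, so decoded speed never
  reaches zero; at rest this leaves a small systematic drift in integrated
  position (visible as higher ME/MV for the hybrid than for the standard
  Kalman filter, whose rest velocity errors are zero-mean).
- ODC/MDC follow the functional glosses "consistency toward the target" /
  "smoothness": ODC counts along-axis reversals, MDC perpendicular
  reversals.  Comparisons with other implementations should check this
  mapping, plus the zero-increment rule (zeros inherit the previous
  nonzero sign; leading zeros are skipped).
- Covariance estimates use dense unregularized residual covariances; with
  very few training samples per channel count, Q can be ill-conditioned
  (the decoder then falls back from the information-form fast path to the
  standard update).
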