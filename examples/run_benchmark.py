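"""Cross-validated decoder benchmark on a reduced synthetic session.

Runs the full protocol — 5-fold trial-wise cross-validation, both
movement regimes (reach+rest vs reach-only), all three decoders — on a
smaller session so it finishes in under a minute, and prints the
summary table (mean over held-out trials) plus a paired significance
test.  Use ``reachbench benchmark --out DIR`` for the full-size run.
"""

from reachbench import BenchmarkConfig, SyntheticConfig, run_benchmark

cfg = BenchmarkConfig(
    synthetic=SyntheticConfig(trials_per_target=10, n_channels=24),
    mlp_max_iter=200,
)
report = run_benchmark(cfg, seed=0)

table = report.summary.pivot_table(index="decoder",
                                   columns=["regime", "metric"],
                                   values="mean")
print(table.round(2).to_string())

speed = report.comparisons.query(
    "regime == 'reach_rest' and metric == 'rmse_speed' "
    "and decoder_a == 'hybrid' and decoder_b == 'kalman'").iloc[0]
print(f"\nreach+rest speed RMSE, hybrid {speed.mean_a:.2f} vs "
      f"kalman {speed.mean_b:.2f} cm/s (paired t-test p = {speed.p:.2g})")
print("Columns: per-trial position/speed RMSE and the four task-axis")
print("pointing metrics, averaged over held-out trials of each regime.")
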