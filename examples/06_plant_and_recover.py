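"""Plant a single effect and check the pipeline recovers it.

Ten replicate cohorts (n = 30) carry exactly one systematic link: a
standardized slope of 0.6 from unpaced motor variability to Coda CC
compensation.  The harness tabulates which predictor each Coda CC tree
splits on first and how the confirmatory OLS coefficient compares with
the plant.
"""

from rhythmcomp import run_recovery
from rhythmcomp.validation import recovery_run_config

config = recovery_run_config(planted_slope=0.6, n_participants=30, seed=11)
result = run_recovery(config, n_replicates=10)

sel = result.selection_frequency
print("Coda CC first-split selection frequencies:")
for _, row in sel[sel["segment"] == "CodaCC"].iterrows():
    name = row["first_split"] or "(root only)"
    print(f"  {name:22s} {row['frequency']:.0%}")

est = result.estimation
row = est[(est.segment == "CodaCC") & (est.predictor == "unpaced_motor_var_z")].iloc[0]
print(f"\nplanted standardized slope: {row['planted']:.2f}")
print(f"mean recovered coefficient: {row['mean_coef']:.2f} "
      f"(bias {row['bias']:+.2f}, RMSE {row['rmse']:.2f}, "
      f"over {row['n_estimates']} replicates)")
# The planted predictor should dominate the first splits and the
# recovered standardized coefficient should sit near 0.6; residual
# shrinkage reflects measurement noise in the tapping-derived predictor.
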