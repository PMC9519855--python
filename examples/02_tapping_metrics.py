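"""Clean a finger-tapping series and compute motor-variability metrics.

A virtual participant taps to a 600 ms metronome for 60 s with a target
inter-tap-interval cv of 0.05 plus occasional pad bounces.  Cleaning
discards the first ten taps, removes sub-100 ms artifacts and mean±3SD
outliers; the summary is the mean ITI and its coefficient of variation.
"""

import numpy as np

from rhythmcomp import tapping
from rhythmcomp.cohort import SEGMENT_LABELS, TapTaskSpec, TraitProfile, simulate_tap_series

trait = TraitProfile(
    participant_id="demo",
    acuity_general=0.0,
    acuity_bat=0.0,
    motor_var_paced=0.05,
    motor_var_unpaced=0.06,
    lapse_rate=0.02,
    false_alarm_rate=0.1,
    compensation_true=dict.fromkeys(SEGMENT_LABELS, 0.0),
)

rng = np.random.default_rng(1)
series = simulate_tap_series(
    trait, TapTaskSpec("metro_600", 600.0, 60.0), rng, artifact_rate=0.03
)
itis = tapping.clean_itis(series)
summary = tapping.summarize(itis)

print(f"taps recorded:        {len(series.tap_times_ms)}")
print(f"ITIs retained:        {len(itis.itis_ms)} "
      f"({itis.n_removed_artifact} artifacts, {itis.n_removed_outlier} outliers removed)")
print(f"mean ITI:             {summary.mean_iti_ms:.1f} ms (pacing IOI 600 ms)")
print(f"cv of ITI:            {summary.cv_iti:.4f} (target 0.05)")
# The cv estimate sits close to the generating target; it is the
# motor-variability measure used as a model predictor downstream.
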