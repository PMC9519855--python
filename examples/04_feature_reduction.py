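"""Reduce the task batteries to the four model predictors.

A 40-participant synthetic cohort yields five perception thresholds and
nine tapping cvs per person.  KMO sampling adequacy screens each
battery, PCA on the correlation matrix (Kaiser retention) extracts the
component scores, and the unpaced cv is z-normalized, giving the four
predictors used in the predictive models.
"""

import dataclasses

import numpy as np

from rhythmcomp.cohort import CohortConfig, generate_cohort
from rhythmcomp.features import loading_cutoff
from rhythmcomp.pipeline import RunConfig, reduce_features, score_staircases, summarize_tapping

config = dataclasses.replace(CohortConfig(), n_participants=40, seed=3)
data = generate_cohort(config)
thresholds = score_staircases(data.staircase_logs)
tapping = summarize_tapping(data.tap_series, RunConfig().cleaning)

(p_msa, p_pca), (t_msa, t_pca), reduced = reduce_features(thresholds, tapping)

print(f"perception battery: overall MSA {p_msa.overall_msa:.2f}, "
      f"excluded tasks {list(p_msa.excluded_tasks) or 'none'}")
print(f"tapping battery:    overall MSA {t_msa.overall_msa:.2f}, "
      f"excluded tasks {list(t_msa.excluded_tasks) or 'none'}")
print(f"perception eigenvalues: {np.round(p_pca.eigenvalues, 2)} "
      f"-> {p_pca.retained} Kaiser component(s)")
print(f"tapping eigenvalues:    {np.round(t_pca.eigenvalues, 2)} "
      f"-> {t_pca.retained} Kaiser component(s)")
cut = loading_cutoff(len(p_pca.tasks))
print(f"perception loading cutoff sqrt(1/{len(p_pca.tasks)}) = {cut:.3f}; "
      f"important on PC1: {p_pca.flagged_loadings().get('PC1')}")
print("\npredictors (first five participants):")
print(reduced.predictors.head().round(2).to_string())
# An MSA above 0.5 qualifies a battery/task; components with eigenvalue
# above 1 are retained. Higher pc1_auditory_acuity means better
# perception; higher motor-variability predictors mean less stable tapping.
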