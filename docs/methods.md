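# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `rhythmcomp`. Everything quantitative stated here is
computed by the test suite (`tests/`) or the validation experiments
(`rhythmcomp.validation`, driven by `scripts/acceptance.py`); nothing is
asserted that the code does not measure.

## 1. Adaptive staircase

**Procedure.** A trial presents a stimulus pair differing by *delta* (ms).
A correct identification triggers a re-presentation at the same delta; two
correct responses in a row complete a *success* and the delta is multiplied
by 0.5, a single error completes a *failure* and multiplies it by 1.5.
Deltas are rounded to 1 ms, floored at 1 ms and capped at the start delta
(the rounding grid and floor/cap are implementation conventions; the
protocol itself fixes only the 1 ms resolution). A *reversal* is an outcome
whose quality differs from the preceding outcome's; its recorded delta is
the delta at which the changed outcome completed. Runs stop at 12 reversals
(discrimination) or 8 (beat alignment). Catch trials (delta 0) are placed at
uniformly random attempt slots within a nominal horizon of 35 attempts; slots
falling after termination are not presented, and incomplete final attempts
never enter catch statistics. The acuity score is the mean of the six
consecutive reversals with the lowest sample SD (earliest window on ties);
a run is valid when more than half the presented catch trials were answered
correctly and the score fell below 70% of the start delta.

**Observer model.** Simulated listeners respond with
P(correct | delta) = 0.5 + (0.5 − lapse)·F((ln δ − ln θ)/s),
F the logistic CDF, θ the listener's threshold and s the spread in
log-delta. At δ = θ a lapse-free observer is 75% correct. Catch trials are
answered "different" with the false-alarm probability. Defaults: s = 0.15
(chosen from typical duration-discrimination Weber fractions of 10–15%: the
75%→95% span is then a delta factor of ≈ 1.7), lapse 0.02, false-alarm 0.10.

**Statistical properties worth knowing.** Two properties of this protocol
are easy to underestimate and are measured by the validation experiments
rather than assumed away:

1. *Convergence point.* The ×0.5/×1.5 steps are asymmetric on the log scale
   (|ln 0.5| = 0.69 vs ln 1.5 = 0.41). Setting the per-outcome drift to zero,
   the track concentrates where P(correct)² = ln 1.5 / ln 3, i.e. at ≈ 60.7%
   correct — *below* the classic 70.7% of the equal-step transformed up-down
   rule. The lowest-SD window selection additionally favours low-delta
   windows (smaller deltas have smaller linear SDs). The measured median
   score is therefore ≈ 0.73–0.79 of the 70.7%-correct delta, right at the
   edge of a ±25% band around it.
2. *Score reliability.* Below threshold the observer still guesses at 50%,
   so runs of lucky successes carry the track far under θ. With 12 reversals
   the log-scale SD of the score is ≈ 0.5–0.7 regardless of the observer's
   slope — an inherent ceiling on rank-recovery of thresholds (Spearman
   ≈ 0.85 across 45 observers spanning 20–400 ms; a 0.9 target is reached
   only at favourable seeds). This is the motivation, visible in the
   validation numbers, for preferring AABA-style designs over 2I designs
   with catch trials.

## 2. Tapping

**Generator.** Tap times follow a two-level timing model: ITI_n = C_n +
M_{n+1} − M_n with central intervals C (mean IOI, variance σc²) and motor
delays M (variance σm²), giving Var(ITI) = σc² + 2σm² and the lag-1 negative
ITI covariance (−σm²) characteristic of tapping. The variance budget
(cv·IOI)² allocates 2σm² = 40% (σm² = 0.2 budget); unpaced tapping
additionally carries a reflected-random-walk drift on C worth 10% of the
budget (bound b = √(3·0.1)·cv·IOI, step b/5), and its tempo is self-chosen
(log-normal around 600 ms, sd 0.10). Optional pad bounces (extra taps
30–80 ms after a true tap) exercise artifact cleaning. Because the variance
identities are exact, the cleaned cv estimate recovers the target cv with a
median relative error of ≈ 5–7% at 90 ITIs (≤ 10% for cv ∈ {0.02, 0.05,
0.10}).

**Cleaning.** First ten *taps* (not ITIs) discarded; ITIs < 100 ms removed
as artifacts; outliers removed outside mean ± 3 SD computed once on the
artifact-free intervals (single pass, per participant and task — battery
descriptions in this field name outlier removal without a formula, so
the conventional 3 SD rule is exposed as `CleaningParams.outlier_sd`).
Single-pass bounds make cleaning idempotent.

## 3. Perturbation trials and compensation

**Design.** Per condition (Onset, Coda): 20 baseline, 30 ramp, 30 hold,
30 after-effect trials. The first segment of the perturbed sequence is
stretched, the second compressed. Word-normalized durations (cc/word,
v/word) are the analysis currency.

**Generator.** Baseline proportions carry participant-level offsets
(between-participant SD 0.02) and trial noise (cv 0.06); word duration is
drawn independently (750 ± 40 ms), so the planted percent change of a
proportion is exactly the quantity the measurement stage estimates. The
planted effect ramps linearly to its hold value and persists into the
after-effect phase at a per-condition factor (0.2 for Onset ≈ mostly online
response, 0.9 for Coda ≈ mostly adaptive), a modelling choice — no quantitative after-effect
decay profile is established for this paradigm. Ramp/hold trials are
flagged perturbation-invalid i.i.d. with probability `mistrigger_rate`
(0.25); the flag is generated, not inferred, because the experimental system
logs mis-triggers directly. Real mis-trigger patterns cluster within
speakers; that clustering (and the covariation of word duration with its
segments) is not emulated.

**Measures.** After dropping invalid ramp/hold rows, participants with
< 16 valid hold trials in a condition, and baseline trials 1–9, the
response is 100·(mean_hold − mean_base)/mean_base of the segment's
normalized duration, multiplied by −1 for the stretched first segments
(Onset CC, Coda V) so that positive always opposes the perturbation.
A proportion-point variant (`metric="points"`) is provided because percent
axes in this literature admit either reading; percent change is the
default. The same trial-10–20 baseline window is used for compensation and
for baseline speech variability (cv of the normalized duration), keeping
the two analyses internally consistent. Planted effects are recovered
within ±2 points at small speech noise, and the full pipeline recovers a
planted standardized slope with ≈ 3–15% error in the confirmatory
coefficient (median over replicates).

## 4. Latent traits and planted effects

Four latent traits (general auditory acuity, beat-alignment acuity, paced
and unpaced motor variability) are multivariate normal with unit-diagonal
correlation matrix (defaults: 0.4 within the perception block, 0.5 within
the motor block); motor cvs and task thresholds live on the log scale for
positivity. Task observables attenuate the latents realistically: task
thresholds are θ_ref·exp(−0.5·Σw·z + jitter) with task-specific log jitter
0.25 (perception) and target cvs carry log jitter 0.15 (tapping),
magnitudes consistent with psychophysical and tapping test–retest
reliabilities. Planted compensation is

comp_true(segment) = μ_seg + 10·Σ_p β_p·z_p + N(0, 8²)  [%],

so with the default scale (10% per trait SD) and residual (8%), a β of 0.6
*is* the trait-level predictor–response correlation (6/√(36+64) = 0.6).
Default μ/β values mirror the qualitative structure this paradigm reports
(perception latents drive Onset responses, unpaced motor variability
drives Coda responses, total response SD ≈ 10%, confirmatory adjusted R²
for Coda CC in the 0.2–0.5 range at n ≈ 30).

## 5. Feature reduction

KMO/MSA from the inverse correlation matrix (ridge 1e-8 added only when the
condition number exceeds 1e10, so well-conditioned matrices match closed
forms exactly); tasks with MSA < 0.5 are excluded and a battery qualifies
at overall MSA > 0.5. At n ≈ 30 the sample MSA of a realistically noisy
battery fluctuates by ±0.2, so the pipeline falls back to the full battery
(with a logged warning) when the gate would leave fewer than two tasks —
the gate itself is unchanged otherwise. knn imputation (k = 5, a
conventional choice) fills at most one missing task
per participant using Euclidean distance on z-scaled shared columns.
PCA is an eigendecomposition of the correlation matrix; components with
eigenvalue > 1 are retained (the perception battery always also exposes
PC1/PC2 scores since both serve as predictors); components are oriented so
loading sums are ≤ 0 for perception (higher score = better perception) and
≥ 0 for tapping. Loadings with |value| > √(1/p) are flagged important.
95%-interval outliers (strictly outside mean ± 1.96 SD, a normal-interval
convention) become missing; participants missing more
than one predictor are excluded, single holes are knn-imputed; response
(compensation) values are *never* imputed.

## 6. Regression trees and confirmatory OLS

`best_split` scans every predictor and every midpoint of consecutive
distinct sorted values, minimizing the summed child SSE subject to
minbucket = 4 on both children; ties break to the lower predictor index and
lower threshold (verified exhaustively against brute-force enumeration).
A split is kept when it reduces total SSE by at least cp·SSE(root)
(per-model defaults 0.1/0.15/0.15/0.1; the conventional relative-error
formulation of the cost-complexity gate). Re-splitting on an already-used
predictor can be suppressed (`allow_repeated_predictors=False`), a common guard
against piecewise overfitting of a single predictor. Cross-validation (`cv_error`) assigns folds
by a seeded uniform permutation chunked into 10 folds and reports held-out
SSE divided by root SSE, averaged over 3 repetitions; `prune="cv"` replaces
a grown tree by its root when it fails to beat the root mean on that score.

**A caution the validation experiments quantify.** With n ≈ 30, four
predictors and minbucket 4, the *maximally selected* split on pure-noise
data reduces SSE by ≥ 10% of the root SSE in ≈ 90% of datasets — so with
the per-split gate alone (the default, matching the described modelling
choices) trees regularly split null data, and a null-control replication
finds all four trees root-only in ≈ 0% of replicates (per-tree ≈ 15–19%).
CV pruning suppresses null splits to ≈ 5–7% per tree but also costs real
power (planted-predictor selection drops from ≈ 0.9 to ≈ 0.6–0.7 at a
standardized slope of 0.6). Both behaviours are inherent to maximally
selected statistics at this sample size, not implementation artifacts; the
package exposes both gates and the validation suite reports both numbers.

The confirmatory model regresses the response on the tree-selected
predictors with their pairwise interaction products, via OLS with
intercept, reporting coefficient SE/t/p, the overall F on (p, n − p − 1)
df, R² and adjusted R² (verified to 1e-8 against normal equations plus
scipy's t/F distribution functions; statsmodels performs the fit).

## 7. Pipeline, seeds and the recovery experiment

`run_study` executes simulate → staircase scoring → tapping summaries →
compensation (+ inter-measure and baseline-variability regressions) →
feature reduction → trees + OLS. One master seed feeds a `SeedSequence`
tree with child streams per participant, task and stage, so identical
configurations reproduce bit-identical bundles and any stage can be re-run
from its persisted CSVs. `run_recovery` derives one sub-seed per replicate
and tabulates first-split selection frequencies and standardized
coefficient bias/RMSE against the planted values.

The *isolated plant* experiment (`validation.recovery_run_config`) plants a
single standardized slope 0.6 from unpaced motor variability to Coda CC at
n = 30 and zeroes the paced↔unpaced trait correlation: with the default 0.5
correlation the paced-tapping PC is a genuine competitor for the first
split and the "single effect" premise would not hold. Perception-block
correlations stay at their defaults (they are orthogonal to the planted
path and the perception battery needs them to remain factorable). Measured
over 100-replicate runs, the planted predictor leads the Coda CC tree in
≈ 74–90% of replicates (the loss relative to the ≈ 92% of an idealized
direct-tree simulation reflects honest attenuation: the predictor is
estimated from ≈ 90 ITIs and both predictors and responses pass the
95%-interval outlier trim) and the mean standardized coefficient lands
within 3–15% of 0.6.

## 8. Problem sizes

Validation experiments use the sizes their definitions state: 200 staircase
runs (convergence), 45 observers (recovery), 100 series per cv target
(tapping), 50 random datasets (tree oracle), and 100 replicates of the
n = 30 pipeline for the plant and null experiments; these sizes keep the
full validation suite to a few minutes on one CPU while holding Monte-Carlo
standard errors on the reported proportions near 3–4 points.

## 9. What passing tests do and do not show

The generator produces the *design* of the study — schedules, gates, task
batteries, plausible noise magnitudes and a recoverable causal structure —
not recorded speech. Passing plant-and-recover tests show the measurement
chain is unbiased and the model-selection stage has the claimed operating
characteristics *under the generator's assumptions* (log-normal traits,
i.i.d. trial noise, linear trait→compensation links). They do not certify
performance under real-data features the generator omits: speaker-clustered
mis-triggers, non-stationary speech rate, segment–word duration covariation,
non-logistic psychometric functions, or missing-not-at-random task dropout.
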