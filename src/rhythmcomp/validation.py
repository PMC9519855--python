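"""Validation experiments: known-truth checks of the whole toolchain.

Each function runs a self-contained experiment against an independent
oracle (closed form, exhaustive enumeration, or planted ground truth)
and returns plain numbers:

* staircase convergence against the classic 70.7%-correct point of the
  transformed up-down method, and threshold-rank recovery;
* tapping cv calibration and artifact cleaning;
* KMO closed forms and partial-correlation oracles;
* exhaustive-enumeration equivalence of the tree split search;
* normal-equations/distribution-function checks of the OLS reporting;
* end-to-end plant-and-recover and null-control replications.

The oracles here are deliberately written as naive, readable code paths
(double loops, closed forms) independent of the package implementations
they check.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from . import features as feat
from . import models as mdl
from . import staircase as sc
from . import tapping as tp
from .cohort import TapTaskSpec, TraitProfile, simulate_response, simulate_tap_series
from .pipeline import RunConfig, run_recovery

__all__ = [
    "logistic_observer",
    "staircase_convergence",
    "threshold_recovery",
    "tapping_cv_recovery",
    "kmo_checks",
    "tree_split_oracle_check",
    "ols_oracle_check",
    "plant_recovery_experiment",
    "null_control_experiment",
    "recovery_run_config",
]

_SEGS = ("OnsetCC", "OnsetV", "CodaV", "CodaCC")


def _trait(lapse=0.0, false_alarm=0.1):
    return TraitProfile(
        participant_id="OBS",
        acuity_general=0.0,
        acuity_bat=0.0,
        motor_var_paced=0.05,
        motor_var_unpaced=0.05,
        lapse_rate=lapse,
        false_alarm_rate=false_alarm,
        compensation_true=dict.fromkeys(_SEGS, 0.0),
    )


def logistic_observer(theta_ms, slope, rng, lapse=0.0):
    trait = _trait(lapse=lapse)

    def responder(delta_ms, is_catch):
        return simulate_response(
            trait, "discrimination", delta_ms, is_catch, rng,
            theta_ms=theta_ms, slope=slope,
        )

    return responder


def staircase_convergence(
    seed: int,
    n_runs: int = 200,
    theta_ms: float = 100.0,
    slope: float = 0.15,
    start_delta_ms: float = 600.0,
) -> dict:
    """Median acuity score vs the 70.7%-correct delta of a lapse-free observer.

    For the transformed 2-down/1-up rule with equal log steps the track
    concentrates at P(correct) = √0.5 ≈ 0.707; the target delta solves
    0.5 + 0.5·F((ln δ − ln θ)/s) = 0.707.
    """
    rng = np.random.default_rng(seed)
    p = math.sqrt(0.5)
    F = 2 * p - 1  # logistic CDF value at the target
    target = theta_ms * math.exp(slope * math.log(F / (1 - F)))
    scores = []
    for _ in range(n_runs):
        cfg = sc.StaircaseConfig(start_delta_ms=start_delta_ms, stop_reversals=12)
        log = sc.run_staircase(logistic_observer(theta_ms, slope, rng), cfg, rng)
        scores.append(sc.estimate_threshold(log).acuity_score_ms)
    median = float(np.median(scores))
    return {
        "median_score_ms": median,
        "target_delta_ms": target,
        "ratio": median / target,
        "abs_rel_err_pct": 100.0 * abs(median / target - 1.0),
        "n": n_runs,
    }


def threshold_recovery(
    seed: int,
    n_observers: int = 45,
    lo_ms: float = 20.0,
    hi_ms: float = 400.0,
    slope: float = 0.15,
) -> dict:
    """Spearman rank agreement between true and estimated thresholds."""
    rng = np.random.default_rng(seed)
    true = np.exp(rng.uniform(math.log(lo_ms), math.log(hi_ms), size=n_observers))
    est = []
    for theta in true:
        cfg = sc.StaircaseConfig(start_delta_ms=600.0, stop_reversals=12)
        log = sc.run_staircase(logistic_observer(theta, slope, rng), cfg, rng)
        est.append(sc.estimate_threshold(log).acuity_score_ms)
    rho = stats.spearmanr(true, est).statistic
    return {"spearman": float(rho), "n": n_observers}


def tapping_cv_recovery(
    seed: int,
    targets: tuple[float, ...] = (0.02, 0.05, 0.10),
    n_series: int = 100,
) -> dict:
    """Median relative error of the cleaned cv estimate per target cv,
    plus the fraction of planted sub-100 ms artifacts removed."""
    rng = np.random.default_rng(seed)
    task = TapTaskSpec("metro_600", 600.0, 60.0)
    med_errs = {}
    for target in targets:
        trait = dataclasses.replace(_trait(), motor_var_paced=target)
        errs = []
        for _ in range(n_series):
            series = simulate_tap_series(trait, task, rng)
            cv = tp.summarize(tp.clean_itis(series)).cv_iti
            errs.append(abs(cv - target) / target)
        med_errs[target] = float(np.median(errs))
    planted = removed = 0
    trait = dataclasses.replace(_trait(), motor_var_paced=0.05)
    for _ in range(50):
        series = simulate_tap_series(trait, task, rng, artifact_rate=0.05)
        raw = np.diff(np.asarray(series.tap_times_ms)[10:])
        planted += int((raw < 100).sum())
        removed += tp.clean_itis(series).n_removed_artifact
    return {
        "median_rel_err": med_errs,
        "worst_median_rel_err": max(med_errs.values()),
        "artifact_removed_fraction": removed / planted if planted else 1.0,
        "n": n_series,
    }


def kmo_checks() -> dict:
    """Closed-form KMO checks: p = 2 exactness and a 3-variable oracle."""
    two_task = feat.kmo(np.array([[1.0, 0.4], [0.4, 1.0]])).overall_msa
    R = np.array([[1.0, 0.55, 0.30], [0.55, 1.0, 0.45], [0.30, 0.45, 1.0]])
    rep = feat.kmo(R)
    # oracle: 3-variable partial correlations in closed form
    partial = np.eye(3)
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            k = ({0, 1, 2} - {i, j}).pop()
            partial[i, j] = (R[i, j] - R[i, k] * R[j, k]) / math.sqrt(
                (1 - R[i, k] ** 2) * (1 - R[j, k] ** 2)
            )
    r2 = R**2 - np.eye(3)
    u2 = partial**2 - np.eye(3)
    per_task = r2.sum(axis=1) / (r2.sum(axis=1) + u2.sum(axis=1))
    overall = r2.sum() / (r2.sum() + u2.sum())
    errs = [abs(rep.overall_msa - overall)]
    errs += [
        abs(rep.per_task_msa[t] - per_task[i])
        for i, t in enumerate(rep.per_task_msa)
    ]
    return {
        "two_task_msa": float(two_task),
        "three_task_max_abs_err": float(max(errs)),
    }


def _brute_force_split(X, y, minbucket):
    n = len(y)
    best = None
    for j in range(X.shape[1]):
        uniq = np.unique(X[:, j])
        for a, b in zip(uniq[:-1], uniq[1:]):
            thr = (a + b) / 2
            left = X[:, j] < thr
            nl = int(left.sum())
            if nl < minbucket or n - nl < minbucket:
                continue
            yl, yr = y[left], y[~left]
            sse = np.sum((yl - yl.mean()) ** 2) + np.sum((yr - yr.mean()) ** 2)
            red = np.sum((y - y.mean()) ** 2) - sse
            if red <= 0:
                continue
            if best is None or red > best[2] + 1e-12:
                best = (j, thr, red)
    return best


def tree_split_oracle_check(seed: int, n_datasets: int = 50) -> dict:
    """best_split vs exhaustive enumeration; cp = 1 root-only guarantee."""
    rng = np.random.default_rng(seed)
    agree = root_only = 0
    for _ in range(n_datasets):
        n = int(rng.integers(8, 13))
        X = rng.standard_normal((n, 4))
        y = rng.standard_normal(n)
        ours = mdl.best_split(X, y, minbucket=4)
        oracle = _brute_force_split(X, y, minbucket=4)
        if oracle is None and ours is None:
            agree += 1
        elif (
            oracle is not None
            and ours is not None
            and ours[0] == oracle[0]
            and abs(ours[1] - oracle[1]) < 1e-12
            and abs(ours[2] - oracle[2]) < 1e-9
        ):
            agree += 1
        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=1.0))
        root_only += int(tree.n_splits == 0)
    return {
        "agreement_fraction": agree / n_datasets,
        "cp1_root_only_fraction": root_only / n_datasets,
        "n": n_datasets,
    }


def ols_oracle_check(seed: int) -> dict:
    """fit_ols vs a normal-equations + t/F-distribution oracle."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["u", "v"])
    y = 1.0 + 0.8 * X["u"] - 0.5 * X["v"] + 0.3 * X["u"] * X["v"]
    y = (y + rng.standard_normal(10)).to_numpy()
    fit = mdl.fit_ols(X, y, include_interactions=True)

    Xd = np.column_stack([np.ones(10), X["u"], X["v"], X["u"] * X["v"]])
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    beta = XtX_inv @ Xd.T @ y
    resid = y - Xd @ beta
    n, p = 10, 3
    dof = n - p - 1
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    pv = 2 * stats.t.sf(np.abs(t), dof)
    sst = np.sum((y - y.mean()) ** 2)
    sse = float(resid @ resid)
    r2 = 1 - sse / sst
    adj = 1 - (1 - r2) * (n - 1) / dof
    f = ((sst - sse) / p) / (sse / dof)
    fp = stats.f.sf(f, p, dof)

    errs = []
    for k, (b, s_, t_, p_) in zip(fit.terms, zip(beta, se, t, pv)):
        errs += [
            abs(fit.coefficients[k] - b),
            abs(fit.std_errors[k] - s_),
            abs(fit.t_values[k] - t_),
            abs(fit.p_values[k] - p_),
        ]
    errs += [
        abs(fit.f_statistic - f),
        abs(fit.f_pvalue - fp),
        abs(fit.r2 - r2),
        abs(fit.adj_r2 - adj),
    ]

    xp = np.arange(5, dtype=float)
    perfect = mdl.fit_ols(pd.DataFrame({"x": xp}), 2 * xp, include_interactions=False)
    return {
        "max_abs_err": float(max(errs)),
        "perfect_fit_adj_r2": perfect.adj_r2,
        "perfect_fit_slope": perfect.coefficients["x"],
    }


def recovery_run_config(
    planted_slope: float = 0.6,
    n_participants: int = 30,
    seed: int = 0,
) -> RunConfig:
    """Study configuration for the isolated plant-and-recover experiment.

    The paced↔unpaced motor-trait correlation is zeroed so the planted
    path (unpaced motor variability → Coda CC compensation) is the only
    systematic predictor–response link; the perception-block correlation
    is irrelevant to that path and kept at its default.
    """
    corr = (
        (1.0, 0.4, 0.0, 0.0),
        (0.4, 1.0, 0.0, 0.0),
        (0.0, 0.0, 1.0, 0.0),
        (0.0, 0.0, 0.0, 1.0),
    )
    effects = (
        {"CodaCC": {"motor_var_unpaced": planted_slope}} if planted_slope else {}
    )
    base = RunConfig()
    cohort = dataclasses.replace(
        base.cohort,
        n_participants=n_participants,
        trait_correlations=corr,
        effect_sizes=effects,
    )
    return dataclasses.replace(base, cohort=cohort).with_seed(seed)


def plant_recovery_experiment(seed: int, n_replicates: int = 100) -> dict:
    """Full-pipeline recovery of a single planted standardized slope."""
    cfg = recovery_run_config(planted_slope=0.6, seed=seed)
    res = run_recovery(cfg, n_replicates)
    sel = res.selection_frequency
    row = sel[
        (sel["segment"] == "CodaCC") & (sel["first_split"] == "unpaced_motor_var_z")
    ]
    sel_freq = float(row["frequency"].iloc[0]) if len(row) else 0.0
    est = res.estimation
    row = est[
        (est["segment"] == "CodaCC") & (est["predictor"] == "unpaced_motor_var_z")
    ].iloc[0]
    return {
        "selection_frequency": sel_freq,
        "mean_coef_std": float(row["mean_coef"]),
        "coef_rel_err": abs(float(row["mean_coef"]) - 0.6) / 0.6,
        "n": n_replicates,
    }


def null_control_experiment(seed: int, n_replicates: int = 100) -> dict:
    """All effect sizes zero: how often do the four trees stay root-only?"""
    cfg = recovery_run_config(planted_slope=0.0, seed=seed)
    res = run_recovery(cfg, n_replicates)
    reps = res.replicates
    all_four = float((reps.groupby("replicate")["n_splits"].max() == 0).mean())
    per_tree = float((reps["n_splits"] == 0).mean())
    return {
        "all_four_root_only_fraction": all_four,
        "per_tree_root_only_fraction": per_tree,
        "n": n_replicates,
    }
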