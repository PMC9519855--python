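"""End-to-end study pipeline and replication harness.

``run_study`` chains cohort simulation → staircase scoring → tapping
summaries → compensation measures → feature reduction → regression
trees + confirmatory OLS, all under a single master seed.
``run_recovery`` repeats the study over derived seeds and tabulates how
often each tree's first split picks each predictor and how well the
planted effect sizes are re-estimated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import compensation as comp
from . import features as feat
from . import models as mdl
from . import staircase as sc
from . import tapping as tap
from .cohort import SEGMENT_LABELS, CohortConfig, CohortData, generate_cohort

__all__ = ["RunConfig", "ReportBundle", "RecoveryResult", "run_study", "run_recovery"]

log = logging.getLogger("rhythmcomp")

#: map from effect-size trait names to assembled predictor columns
TRAIT_TO_PREDICTOR = {
    "acuity_general": "pc1_auditory_acuity",
    "acuity_bat": "pc2_bat_perception",
    "motor_var_paced": "pc1_paced_motor_var",
    "motor_var_unpaced": "unpaced_motor_var_z",
}


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cleaning: tap.CleaningParams = field(default_factory=tap.CleaningParams)
    tree_params: dict[str, mdl.TreeParams] = field(
        default_factory=lambda: {
            "OnsetCC": mdl.TreeParams(cp=0.10),
            "OnsetV": mdl.TreeParams(cp=0.15),
            "CodaV": mdl.TreeParams(cp=0.15),
            "CodaCC": mdl.TreeParams(cp=0.10),
        }
    )
    knn_k: int = 5
    outlier_z: float = 1.96
    min_hold_valid: int = 16
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed), cohort=replace(self.cohort, seed=int(seed)))

    def config_hash(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    thresholds: pd.DataFrame  # participant_id, task, acuity_score_ms, valid
    tapping_summary: pd.DataFrame
    compensation: pd.DataFrame
    baseline_cv: pd.DataFrame
    intercorrelations: pd.DataFrame
    speech_variability: pd.DataFrame
    perception_msa: feat.MSAReport
    tapping_msa: feat.MSAReport
    perception_pca: feat.PCAResult
    tapping_pca: feat.PCAResult
    features: feat.ReducedFeatures
    trees: dict[str, mdl.TreeModel]
    tree_cv_error: dict[str, float]
    ols: dict[str, mdl.OLSFit | None]
    model_frames: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.thresholds.to_csv(out / "thresholds.csv", index=False)
        self.tapping_summary.to_csv(out / "tapping_summary.csv", index=False)
        self.compensation.to_csv(out / "compensation.csv", index=False)
        self.baseline_cv.to_csv(out / "baseline_cv.csv", index=False)
        self.intercorrelations.to_csv(out / "intercorrelations.csv", index=False)
        self.speech_variability.to_csv(out / "speech_variability.csv", index=False)
        self.features.predictors.to_csv(out / "features.csv")
        report = {
            "perception": {
                "overall_msa": self.perception_msa.overall_msa,
                "per_task_msa": self.perception_msa.per_task_msa,
                "excluded_tasks": list(self.perception_msa.excluded_tasks),
                "eigenvalues": self.perception_pca.eigenvalues.tolist(),
                "retained": self.perception_pca.retained,
                "loadings": self.perception_pca.loadings.tolist(),
                "tasks": list(self.perception_pca.tasks),
                "flagged_loadings": self.perception_pca.flagged_loadings(),
            },
            "tapping": {
                "overall_msa": self.tapping_msa.overall_msa,
                "per_task_msa": self.tapping_msa.per_task_msa,
                "excluded_tasks": list(self.tapping_msa.excluded_tasks),
                "eigenvalues": self.tapping_pca.eigenvalues.tolist(),
                "retained": self.tapping_pca.retained,
                "loadings": self.tapping_pca.loadings.tolist(),
                "tasks": list(self.tapping_pca.tasks),
                "flagged_loadings": self.tapping_pca.flagged_loadings(),
            },
            "excluded_participants": self.features.excluded_participants,
        }
        (out / "pca_report.json").write_text(json.dumps(report, indent=2))
        trees = {seg: m.root.to_dict() for seg, m in self.trees.items()}
        (out / "tree.json").write_text(json.dumps(trees, indent=2))
        lm = {
            seg: (fit.to_dict() if fit is not None else None)
            for seg, fit in self.ols.items()
        }
        (out / "lm_report.json").write_text(json.dumps(lm, indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


# ---------------------------------------------------------------------------
# stage helpers (each usable on loaded CSVs as well as generated data)
# ---------------------------------------------------------------------------

def score_staircases(logs: dict[tuple[str, str], sc.StaircaseLog]) -> pd.DataFrame:
    rows = []
    for (pid, task), slog in logs.items():
        est = sc.estimate_threshold(slog)
        rep = sc.check_validity(slog, est)
        rows.append(
            {
                "participant_id": pid,
                "task": task,
                "acuity_score_ms": est.acuity_score_ms,
                "valid": int(rep.valid),
            }
        )
    return pd.DataFrame(rows)


def summarize_tapping(
    tap_series: dict[tuple[str, str], tap.TapSeries],
    cleaning: tap.CleaningParams,
) -> pd.DataFrame:
    rows = []
    for (pid, task), series in tap_series.items():
        itis = tap.clean_itis(series, cleaning)
        summary = tap.summarize(itis)
        rows.append(
            {
                "participant_id": pid,
                "task": task,
                "mean_iti_ms": summary.mean_iti_ms,
                "cv_iti": summary.cv_iti,
                "n_removed_artifact": itis.n_removed_artifact,
                "n_removed_outlier": itis.n_removed_outlier,
            }
        )
    return pd.DataFrame(rows)


def reduce_features(
    thresholds: pd.DataFrame,
    tapping_summary: pd.DataFrame,
    *,
    knn_k: int = 5,
    outlier_z: float = 1.96,
    max_missing_tasks: int = 1,
):
    """MSA gating, imputation and PCA for both batteries.

    Invalid staircase runs become missing cells; participants missing
    more than ``max_missing_tasks`` cells in a battery are dropped from
    that battery's PCA (the standard pre-processing gate for these batteries).
    """
    thr = thresholds.copy()
    thr.loc[thr["valid"] == 0, "acuity_score_ms"] = np.nan
    perception = thr.pivot(index="participant_id", columns="task", values="acuity_score_ms")
    tapping = tapping_summary.pivot(index="participant_id", columns="task", values="cv_iti")
    unpaced = tapping["unpaced"] if "unpaced" in tapping.columns else pd.Series(dtype=float)
    paced = tapping.drop(columns=["unpaced"], errors="ignore")

    out = {}
    for name, X in (("perception", perception), ("tapping", paced)):
        X = X[X.isna().sum(axis=1) <= max_missing_tasks]
        if X.isna().any().any():
            X = feat.knn_impute(X, k=min(knn_k, len(X.dropna())))
        msa = feat.kmo(X.corr())
        kept = [c for c in X.columns if c not in msa.excluded_tasks]
        if len(kept) < 2:
            # sampling noise can push most per-task MSAs below the gate in
            # small cohorts; fall back to the full battery rather than abort
            log.warning(
                "%s battery: MSA gate left %d task(s); retaining all %d",
                name, len(kept), X.shape[1],
            )
            kept = list(X.columns)
        pca = feat.pca_reduce(
            X[kept],
            orient="negative" if name == "perception" else "positive",
            score_components=2 if name == "perception" else None,
        )
        out[name] = (msa, pca)
        if msa.excluded_tasks:
            log.info("%s battery: MSA-excluded tasks %s", name, msa.excluded_tasks)

    # unpaced cv imputation mirrors the battery treatment
    unpaced = unpaced.copy()
    if unpaced.isna().any():
        helper = pd.concat([paced, unpaced.rename("unpaced")], axis=1)
        helper = helper[helper.isna().sum(axis=1) <= max_missing_tasks]
        helper = feat.knn_impute(helper, k=min(knn_k, len(helper.dropna())))
        unpaced = helper["unpaced"]

    reduced = feat.assemble_predictors(
        out["perception"][1], out["tapping"][1], unpaced, k=knn_k, outlier_z=outlier_z
    )
    return out["perception"], out["tapping"], reduced


def fit_models(
    predictors: pd.DataFrame,
    compensation_table: pd.DataFrame,
    tree_params: dict[str, mdl.TreeParams],
    *,
    outlier_z: float = 1.96,
    seed: int = 0,
):
    """Per segment: response outlier removal, tree, CV error, confirmatory OLS.

    Compensation responses are never imputed; participants lacking a
    response are dropped from that segment's model only.
    """
    trees: dict[str, mdl.TreeModel] = {}
    cv_err: dict[str, float] = {}
    ols: dict[str, mdl.OLSFit | None] = {}
    frames: dict[str, pd.DataFrame] = {}
    for i, seg in enumerate(SEGMENT_LABELS):
        resp = compensation_table[compensation_table["segment_label"] == seg]
        resp = resp.set_index("participant_id")["compensation_pct"]
        keep = feat.ci_outlier_mask(resp, z=outlier_z)
        resp = resp[keep]
        data = predictors.join(resp, how="inner").dropna()
        frames[seg] = data
        y = data["compensation_pct"].to_numpy()
        X = data[list(feat.PREDICTOR_COLUMNS)]
        params = replace(tree_params[seg], seed=seed + i)
        tree = mdl.grow_tree(X, y, params)
        trees[seg] = tree
        cv_err[seg] = (
            mdl.cv_error(X, y, params, seed=params.seed) if len(y) >= params.cv_folds
            else float("nan")
        )
        selected = tree.selected_predictors()
        if selected:
            ols[seg] = mdl.fit_ols(data[selected], y, include_interactions=len(selected) > 1)
        else:
            ols[seg] = None
    return trees, cv_err, ols, frames


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_study(
    config: RunConfig,
    out_dir: str | Path | None = None,
    cohort_data: CohortData | None = None,
) -> ReportBundle:
    """Execute all stages on a generated (or supplied) cohort."""
    cohort_cfg = replace(config.cohort, seed=config.seed)
    data = cohort_data if cohort_data is not None else generate_cohort(cohort_cfg)

    thresholds = score_staircases(data.staircase_logs)
    tapping_summary = summarize_tapping(data.tap_series, config.cleaning)
    filtered = comp.normalize_and_filter(
        data.segment_tables, min_hold_valid=config.min_hold_valid
    )
    comp_table = comp.compensation_table(filtered)
    base_cv = comp.baseline_cv_table(filtered)
    inter = comp.intercorrelate(comp_table)
    speech_var = comp.speech_variability_correlation(
        comp_table, base_cv, outlier_z=config.outlier_z
    )
    (p_msa, p_pca), (t_msa, t_pca), reduced = reduce_features(
        thresholds, tapping_summary, knn_k=config.knn_k, outlier_z=config.outlier_z
    )
    trees, cv_err, ols, frames = fit_models(
        reduced.predictors, comp_table, config.tree_params,
        outlier_z=config.outlier_z, seed=config.seed,
    )
    bundle = ReportBundle(
        thresholds=thresholds,
        tapping_summary=tapping_summary,
        compensation=comp_table,
        baseline_cv=base_cv,
        intercorrelations=inter,
        speech_variability=speech_var,
        perception_msa=p_msa,
        tapping_msa=t_msa,
        perception_pca=p_pca,
        tapping_pca=t_pca,
        features=reduced,
        trees=trees,
        tree_cv_error=cv_err,
        ols=ols,
        model_frames=frames,
        manifest={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_participants": len(data.traits),
            "excluded_participants": reduced.excluded_participants,
        },
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


@dataclass
class RecoveryResult:
    replicates: pd.DataFrame  # seed, segment, first_split, coef_std, n
    selection_frequency: pd.DataFrame  # segment × predictor → fraction
    planted: dict[str, dict[str, float]]
    estimation: pd.DataFrame  # segment × predictor: mean_coef, bias, rmse


def run_recovery(config: RunConfig, n_replicates: int) -> RecoveryResult:
    """Repeat ``run_study`` over derived seeds and score effect recovery.

    Per replicate and segment the first-split predictor is recorded,
    along with the standardized confirmatory OLS coefficient of each
    selected predictor (coefficient divided by the cohort's
    compensation scale, commensurate with the planted standardized
    slopes).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates) % (2**31)
    scale = config.cohort.compensation_scale
    rows = []
    for rep, seed in enumerate(child_seeds):
        bundle = run_study(config.with_seed(int(seed)))
        for seg in SEGMENT_LABELS:
            tree = bundle.trees[seg]
            fit = bundle.ols[seg]
            coefs = {}
            if fit is not None:
                for term, coef in fit.coefficients.items():
                    if term in feat.PREDICTOR_COLUMNS:
                        coefs[term] = coef / scale
            rows.append(
                {
                    "replicate": rep,
                    "seed": int(seed),
                    "segment": seg,
                    "first_split": tree.first_split_variable or "",
                    "n_splits": tree.n_splits,
                    "n": len(bundle.model_frames[seg]),
                    "coefs_std": coefs,
                }
            )
    reps = pd.DataFrame(rows)

    sel = (
        reps.groupby("segment")["first_split"]
        .value_counts(normalize=True)
        .rename("frequency")
        .reset_index()
    )
    planted = {
        seg: {
            TRAIT_TO_PREDICTOR[t]: beta
            for t, beta in config.cohort.effect_sizes.get(seg, {}).items()
        }
        for seg in SEGMENT_LABELS
    }
    est_rows = []
    for seg in SEGMENT_LABELS:
        seg_reps = reps[reps["segment"] == seg]
        predictors = set()
        for c in seg_reps["coefs_std"]:
            predictors.update(c)
        predictors.update(planted[seg])
        for pred in sorted(predictors):
            vals = np.array(
                [c[pred] for c in seg_reps["coefs_std"] if pred in c], dtype=float
            )
            truth = planted[seg].get(pred, 0.0)
            est_rows.append(
                {
                    "segment": seg,
                    "predictor": pred,
                    "planted": truth,
                    "n_estimates": len(vals),
                    "mean_coef": float(vals.mean()) if len(vals) else np.nan,
                    "bias": float(vals.mean() - truth) if len(vals) else np.nan,
                    "rmse": float(np.sqrt(np.mean((vals - truth) ** 2)))
                    if len(vals)
                    else np.nan,
                }
            )
    return RecoveryResult(
        replicates=reps,
        selection_frequency=sel,
        planted=planted,
        estimation=pd.DataFrame(est_rows),
    )
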