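"""Perturbation-response measures from per-trial segment durations.

Word-normalized segment durations (cc/word, v/word) are compared between
the hold phase (maximum perturbation) and the baseline.  Four measures
result — Onset CC, Onset V, Coda V, Coda CC — with the sign flipped for
the stretched first segments (Onset CC, Coda V) so that a positive value
always means opposing the perturbation.  Baseline speech motor
variability is the cv of the normalized durations over baseline trials
10–20.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import SEGMENT_LABELS, SEGMENT_SPEC

__all__ = [
    "CompensationMeasure",
    "BaselineVariability",
    "normalize_and_filter",
    "compute_compensation",
    "baseline_cv",
    "compensation_table",
    "baseline_cv_table",
    "intercorrelate",
]

REQUIRED_COLUMNS = [
    "participant_id", "condition", "trial", "phase",
    "word_ms", "cc_ms", "v_ms", "pert_valid",
]


@dataclass(frozen=True)
class CompensationMeasure:
    participant_id: str
    segment_label: str
    compensation_pct: float
    n_hold_valid: int


@dataclass(frozen=True)
class BaselineVariability:
    participant_id: str
    segment_label: str
    cv_baseline: float


def normalize_and_filter(
    table: pd.DataFrame,
    *,
    min_hold_valid: int = 16,
    baseline_drop: int = 9,
) -> pd.DataFrame:
    """Word-normalize durations and apply the trial/participant gates.

    Adds ``cc_norm``/``v_norm``; drops ramp/hold rows whose perturbation
    missed its target (``pert_valid`` false); drops a participant from a
    condition with fewer than ``min_hold_valid`` valid hold trials; and
    drops the first ``baseline_drop`` baseline trials (speech-rate
    settling).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    df = table.copy()
    bad = df["word_ms"] <= 0
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            "non-positive word duration for participant "
            f"{row['participant_id']} condition {row['condition']} trial {row['trial']}"
        )
    df["cc_norm"] = df["cc_ms"] / df["word_ms"]
    df["v_norm"] = df["v_ms"] / df["word_ms"]
    df["pert_valid"] = df["pert_valid"].astype(bool)

    df = df[~(df["phase"].isin(["ramp", "hold"]) & ~df["pert_valid"])]
    hold_counts = (
        df[df["phase"] == "hold"].groupby(["participant_id", "condition"]).size()
    )
    keep = hold_counts[hold_counts >= min_hold_valid].index
    df = df.set_index(["participant_id", "condition"])
    df = df[df.index.isin(keep)].reset_index()
    df = df[~((df["phase"] == "baseline") & (df["trial"] <= baseline_drop))]
    return df.reset_index(drop=True)


def _phase_means(
    table: pd.DataFrame, participant: str, segment_label: str
) -> tuple[pd.Series, pd.Series, str]:
    condition, seg, _ = SEGMENT_SPEC[segment_label]
    col = f"{seg}_norm"
    sub = table[(table["participant_id"] == participant) & (table["condition"] == condition)]
    return sub[sub["phase"] == "baseline"][col], sub[sub["phase"] == "hold"][col], col


def compute_compensation(
    table: pd.DataFrame,
    participant: str,
    segment_label: str,
    *,
    metric: str = "percent",
) -> CompensationMeasure:
    """Hold-vs-baseline response for one participant and segment.

    ``metric="percent"`` (default): 100·(mean_hold − mean_base)/mean_base
    of the word-normalized duration; ``metric="points"``: 100·(mean_hold
    − mean_base) in proportion points.  The result is sign-flipped for
    the stretched first segments so positive always opposes the shift.
    """
    if segment_label not in SEGMENT_LABELS:
        raise ValueError(f"unknown segment label {segment_label!r}")
    base, hold, _ = _phase_means(table, participant, segment_label)
    if len(base) < 2 or len(hold) == 0:
        raise ValueError(
            f"insufficient baseline/hold rows for {participant} {segment_label}"
        )
    if metric == "percent":
        raw = 100.0 * (hold.mean() - base.mean()) / base.mean()
    elif metric == "points":
        raw = 100.0 * (hold.mean() - base.mean())
    else:
        raise ValueError(f"unknown metric {metric!r}")
    sign = SEGMENT_SPEC[segment_label][2]
    return CompensationMeasure(
        participant_id=participant,
        segment_label=segment_label,
        compensation_pct=float(sign * raw),
        n_hold_valid=int(len(hold)),
    )


def baseline_cv(
    table: pd.DataFrame, participant: str, segment_label: str
) -> BaselineVariability:
    """cv of the word-normalized duration over the retained baseline trials."""
    base, _, _ = _phase_means(table, participant, segment_label)
    if len(base) < 2:
        raise ValueError(f"need at least 2 baseline rows for {participant}")
    return BaselineVariability(
        participant_id=participant,
        segment_label=segment_label,
        cv_baseline=float(base.std(ddof=1) / base.mean()),
    )


def compensation_table(table: pd.DataFrame, *, metric: str = "percent") -> pd.DataFrame:
    """All four measures for every retained participant (long format)."""
    rows = []
    for segment_label in SEGMENT_LABELS:
        condition = SEGMENT_SPEC[segment_label][0]
        pids = table.loc[table["condition"] == condition, "participant_id"].unique()
        for pid in pids:
            m = compute_compensation(table, pid, segment_label, metric=metric)
            rows.append(
                {
                    "participant_id": m.participant_id,
                    "condition": condition,
                    "segment_label": m.segment_label,
                    "compensation_pct": m.compensation_pct,
                    "n_hold_valid": m.n_hold_valid,
                }
            )
    return pd.DataFrame(rows)


def baseline_cv_table(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for segment_label in SEGMENT_LABELS:
        condition = SEGMENT_SPEC[segment_label][0]
        pids = table.loc[table["condition"] == condition, "participant_id"].unique()
        for pid in pids:
            b = baseline_cv(table, pid, segment_label)
            rows.append(
                {
                    "participant_id": pid,
                    "condition": condition,
                    "segment_label": segment_label,
                    "cv_baseline": b.cv_baseline,
                }
            )
    return pd.DataFrame(rows)


def speech_variability_correlation(
    measures: pd.DataFrame,
    cv_table: pd.DataFrame,
    *,
    outlier_z: float = 1.96,
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Relate baseline speech motor variability to compensation per segment.

    For each segment label the baseline cv is regressed against the
    compensation measure over participants holding both, after removing
    per-measure 95%-interval outliers (which are reported, not modelled).
    """
    from .features import ci_outlier_mask

    rows = []
    for seg in SEGMENT_LABELS:
        m = measures[measures["segment_label"] == seg].set_index("participant_id")
        c = cv_table[cv_table["segment_label"] == seg].set_index("participant_id")
        sub = m[["compensation_pct"]].join(c[["cv_baseline"]], how="inner").dropna()
        n_outlier = 0
        if len(sub) >= 3:
            keep = ci_outlier_mask(sub["compensation_pct"], z=outlier_z)
            keep &= ci_outlier_mask(sub["cv_baseline"], z=outlier_z)
            n_outlier = int((~keep).sum())
            sub = sub[keep]
        if len(sub) < min_overlap:
            rows.append(
                {"segment_label": seg, "n": len(sub), "n_outliers_removed": n_outlier,
                 "adj_r2": np.nan, "p_value": np.nan, "estimable": False}
            )
            continue
        fit = sm.OLS(
            sub["compensation_pct"].to_numpy(),
            sm.add_constant(sub["cv_baseline"].to_numpy()),
        ).fit()
        rows.append(
            {
                "segment_label": seg,
                "n": len(sub),
                "n_outliers_removed": n_outlier,
                "adj_r2": float(fit.rsquared_adj),
                "p_value": float(fit.pvalues[1]),
                "estimable": True,
            }
        )
    return pd.DataFrame(rows)


def intercorrelate(measures: pd.DataFrame, *, min_overlap: int = 4) -> pd.DataFrame:
    """Pairwise simple regressions between the four response measures.

    For each unordered pair, participants holding both measures enter an
    OLS of one on the other; adjusted R², residual df and the slope's
    p-value are reported (a pair with fewer than ``min_overlap`` common
    participants is marked not estimable).
    """
    wide = measures.pivot(
        index="participant_id", columns="segment_label", values="compensation_pct"
    )
    rows = []
    for a, b in combinations(SEGMENT_LABELS, 2):
        if a not in wide.columns or b not in wide.columns:
            sub = pd.DataFrame(columns=[a, b])
        else:
            sub = wide[[a, b]].dropna()
        if len(sub) < min_overlap:
            rows.append(
                {"measure_x": a, "measure_y": b, "n": len(sub),
                 "adj_r2": np.nan, "df_resid": np.nan, "p_value": np.nan,
                 "estimable": False}
            )
            continue
        fit = sm.OLS(sub[b].to_numpy(), sm.add_constant(sub[a].to_numpy())).fit()
        rows.append(
            {
                "measure_x": a,
                "measure_y": b,
                "n": len(sub),
                "adj_r2": float(fit.rsquared_adj),
                "df_resid": int(fit.df_resid),
                "p_value": float(fit.pvalues[1]),
                "estimable": True,
            }
        )
    return pd.DataFrame(rows)
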