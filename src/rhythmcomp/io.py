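"""CSV/YAML interchange helpers for the pipeline stages.

All on-disk formats are plain text: comma-separated with a header row,
durations in milliseconds.  These helpers let each CLI stage re-run from
another stage's persisted outputs.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import pandas as pd
import yaml

from . import staircase as sc
from .cohort import CohortConfig, PhasePlan, PerceptionTaskSpec, TapTaskSpec
from .pipeline import RunConfig
from .tapping import CleaningParams, TapSeries

__all__ = [
    "load_run_config",
    "taps_from_csv",
    "staircase_logs_from_csv",
]


def _build(cls, payload: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**payload)


def load_run_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file (any subset of keys) and a seed."""
    cfg = RunConfig()
    if path is not None:
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cohort_payload = payload.pop("cohort", {})
        if "schedule" in cohort_payload:
            cohort_payload["schedule"] = _build(PhasePlan, cohort_payload["schedule"])
        if "perception_tasks" in cohort_payload:
            cohort_payload["perception_tasks"] = tuple(
                _build(PerceptionTaskSpec, t) for t in cohort_payload["perception_tasks"]
            )
        if "tapping_tasks" in cohort_payload:
            cohort_payload["tapping_tasks"] = tuple(
                _build(TapTaskSpec, t) for t in cohort_payload["tapping_tasks"]
            )
        if "trait_means" in cohort_payload:
            cohort_payload["trait_means"] = tuple(cohort_payload["trait_means"])
        if "trait_sds" in cohort_payload:
            cohort_payload["trait_sds"] = tuple(cohort_payload["trait_sds"])
        if "trait_correlations" in cohort_payload:
            cohort_payload["trait_correlations"] = tuple(
                tuple(row) for row in cohort_payload["trait_correlations"]
            )
        cohort = replace(CohortConfig(), **cohort_payload) if cohort_payload else CohortConfig()
        cleaning = _build(CleaningParams, payload.pop("cleaning", {}))
        tree_payload = payload.pop("tree_params", None)
        base = RunConfig()
        if tree_payload is not None:
            tree_params = {
                seg: replace(base.tree_params[seg], **tree_payload.get(seg, {}))
                for seg in base.tree_params
            }
        else:
            tree_params = base.tree_params
        cfg = RunConfig(cohort=cohort, cleaning=cleaning, tree_params=tree_params, **payload)
    if seed is not None:
        cfg = cfg.with_seed(seed)
    return cfg


def taps_from_csv(path: str | Path) -> dict[tuple[str, str], TapSeries]:
    df = pd.read_csv(path)
    out = {}
    for (pid, task), grp in df.groupby(["participant_id", "task"], sort=False):
        out[(str(pid), str(task))] = TapSeries(
            participant_id=str(pid),
            task=str(task),
            tap_times_ms=tuple(grp["tap_time_ms"].astype(float)),
        )
    return out


def staircase_logs_from_csv(path: str | Path) -> dict[tuple[str, str], sc.StaircaseLog]:
    """Rebuild minimal staircase logs (outcomes, reversals, catch stats).

    Only what scoring needs is reconstructed; per-trial attempt
    structure is carried through unchanged.
    """
    df = pd.read_csv(path)
    out = {}
    for (pid, task), grp in df.groupby(["participant_id", "task"], sort=False):
        grp = grp.sort_values("trial")
        non_catch = grp[grp["is_catch"] == 0]
        if non_catch.empty:
            continue
        start = float(non_catch.iloc[0]["delta_ms"])
        outcomes = [
            sc.Outcome(success=row["outcome"] == "success", delta_ms=float(row["delta_ms"]))
            for _, row in grp.iterrows()
            if isinstance(row["outcome"], str) and row["outcome"] in ("success", "failure")
        ]
        reversals = [delta for _, delta in sc.count_reversals(outcomes)] if outcomes else []
        catches = grp[grp["is_catch"] == 1]
        cfg = sc.StaircaseConfig(
            start_delta_ms=start,
            stop_reversals=max(len(reversals), 7),
            n_catch=len(catches),
        )
        log = sc.StaircaseLog(config=cfg, outcomes=outcomes, reversal_deltas=reversals)
        log.n_catch_presented = int(len(catches))
        log.n_catch_correct = int((catches["response"] == 0).sum())
        out[(str(pid), str(task))] = log
    return out
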