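"""Synthetic cohorts of virtual participants.

Generates, from correlated latent traits, the three observable bundles
the study design produces per participant:

* adaptive-staircase trial logs for five perception tasks (three
  duration-discrimination, two beat-alignment), driven by a logistic
  observer in log-delta;
* tap-onset series for nine tapping tasks, driven by a two-level
  (central clock + peripheral motor) timing model with a bounded
  random-walk drift in unpaced tapping;
* per-trial word/segment durations for the two feedback-perturbation
  conditions (Onset, Coda) over a baseline/ramp/hold/after-effect
  schedule, with planted compensation effects.

Latent traits are multivariate normal; strictly positive quantities
(motor cv targets, acuity thresholds) live on the log scale.  The
planted percent compensation of each segment is a linear combination of
standardized traits, so the full pipeline can be scored on how well it
recovers known effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import staircase as sc

__all__ = [
    "SEGMENT_LABELS",
    "TRAIT_NAMES",
    "TraitProfile",
    "PerceptionTaskSpec",
    "TapTaskSpec",
    "PhasePlan",
    "CohortConfig",
    "CohortData",
    "draw_traits",
    "simulate_response",
    "simulate_tap_series",
    "simulate_perturbation_table",
    "generate_cohort",
]

SEGMENT_LABELS = ("OnsetCC", "OnsetV", "CodaV", "CodaCC")
TRAIT_NAMES = ("acuity_general", "acuity_bat", "motor_var_paced", "motor_var_unpaced")

#: segment → (condition, normalized-duration column, sign flip applied so
#: that positive compensation always opposes the perturbation).  The first
#: segment of each condition is stretched (opposing = shortening, flip −1),
#: the second compressed (opposing = lengthening, flip +1).
SEGMENT_SPEC = {
    "OnsetCC": ("Onset", "cc", -1.0),
    "OnsetV": ("Onset", "v", +1.0),
    "CodaV": ("Coda", "v", -1.0),
    "CodaCC": ("Coda", "cc", +1.0),
}


@dataclass(frozen=True)
class TraitProfile:
    participant_id: str
    acuity_general: float  # unitless latent, higher = better discrimination
    acuity_bat: float  # unitless latent, higher = better beat-alignment perception
    motor_var_paced: float  # target cv of paced ITIs, > 0
    motor_var_unpaced: float  # target cv of unpaced ITIs, > 0
    lapse_rate: float
    false_alarm_rate: float
    compensation_true: dict[str, float]  # % per segment label
    #: standardized latents behind the profile, keyed by TRAIT_NAMES
    latent_z: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.motor_var_paced <= 0 or self.motor_var_unpaced <= 0:
            raise ValueError("cv targets must be strictly positive")
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if not 0 <= self.false_alarm_rate <= 0.5:
            raise ValueError("false_alarm_rate must lie in [0, 0.5]")
        if set(self.compensation_true) != set(SEGMENT_LABELS):
            raise ValueError(f"compensation_true must have keys {SEGMENT_LABELS}")


@dataclass(frozen=True)
class PerceptionTaskSpec:
    name: str
    kind: str  # "discrimination" (2I-2AFC) or "beat_alignment" (1I-2AFC)
    start_delta_ms: float
    stop_reversals: int
    theta_ref_ms: float  # cohort-median threshold
    loads: dict[str, float]  # acuity-latent weights driving the threshold


@dataclass(frozen=True)
class TapTaskSpec:
    name: str
    ioi_ms: float | None  # None = unpaced ("free"); base tempo used instead
    duration_s: float
    base_tempo_ms: float = 600.0  # unpaced: median self-chosen tempo


@dataclass(frozen=True)
class PhasePlan:
    baseline: int = 20
    ramp: int = 30
    hold: int = 30
    after: int = 30

    def __post_init__(self) -> None:
        if min(self.baseline, self.ramp, self.hold, self.after) <= 0:
            raise ValueError("phase lengths must be positive")

    @property
    def phases(self) -> list[tuple[str, int]]:
        return [
            ("baseline", self.baseline),
            ("ramp", self.ramp),
            ("hold", self.hold),
            ("after", self.after),
        ]


def default_perception_tasks() -> tuple[PerceptionTaskSpec, ...]:
    return (
        PerceptionTaskSpec("tone", "discrimination", 600.0, 12, 60.0, {"acuity_general": 1.0}),
        PerceptionTaskSpec("onset", "discrimination", 200.0, 12, 50.0, {"acuity_general": 1.0}),
        PerceptionTaskSpec("coda", "discrimination", 150.0, 12, 45.0, {"acuity_general": 1.0}),
        PerceptionTaskSpec(
            "bat_speech", "beat_alignment", 200.0, 8, 80.0,
            {"acuity_general": 0.5, "acuity_bat": 0.8},
        ),
        PerceptionTaskSpec(
            "bat_music", "beat_alignment", 200.0, 8, 70.0,
            {"acuity_general": 0.4, "acuity_bat": 0.9},
        ),
    )


def default_tapping_tasks() -> tuple[TapTaskSpec, ...]:
    return (
        TapTaskSpec("unpaced", None, 60.0),
        TapTaskSpec("metro_600", 600.0, 60.0),
        TapTaskSpec("metro_750", 750.0, 60.0),
        TapTaskSpec("metro_900", 900.0, 60.0),
        TapTaskSpec("music_badine", 600.0, 40.0),
        TapTaskSpec("music_ross", 600.0, 40.0),
        TapTaskSpec("bla_750", 750.0, 45.0),
        TapTaskSpec("wordlist_900", 900.0, 55.0),
        TapTaskSpec("sentence_600", 600.0, 45.0),
    )


def _default_effect_sizes() -> dict[str, dict[str, float]]:
    # Perception latents drive Onset responses, unpaced motor variability
    # drives Coda responses (with a beat-alignment contribution to CodaCC) —
    # the qualitative structure this paradigm reports.
    return {
        "OnsetCC": {"acuity_bat": 0.45, "acuity_general": 0.25},
        "OnsetV": {"acuity_general": 0.40},
        "CodaV": {"motor_var_unpaced": 0.35},
        "CodaCC": {"motor_var_unpaced": 0.55, "acuity_bat": 0.30},
    }


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 45
    #: latent means/sds in TRAIT_NAMES order; motor entries are on the
    #: log-cv scale (positivity), acuity entries are unitless z-latents.
    trait_means: tuple[float, ...] = (0.0, 0.0, math.log(0.04), math.log(0.05))
    trait_sds: tuple[float, ...] = (1.0, 1.0, 0.35, 0.40)
    trait_correlations: tuple[tuple[float, ...], ...] = (
        (1.0, 0.4, 0.0, 0.0),
        (0.4, 1.0, 0.0, 0.0),
        (0.0, 0.0, 1.0, 0.5),
        (0.0, 0.0, 0.5, 1.0),
    )
    effect_sizes: dict[str, dict[str, float]] = field(default_factory=_default_effect_sizes)
    compensation_means: dict[str, float] = field(
        default_factory=lambda: {"OnsetCC": 0.9, "OnsetV": 8.0, "CodaV": 13.3, "CodaCC": 16.7}
    )
    compensation_scale: float = 10.0  # % change per SD of a standardized trait
    noise_sd_compensation: float = 8.0  # % trait-level residual
    mistrigger_rate: float = 0.25
    lapse_rate: float = 0.02
    false_alarm_rate: float = 0.10
    psychometric_slope: float = 0.15  # logistic spread in log-delta
    acuity_spread: float = 0.50  # between-participant SD of log thresholds
    task_jitter_sd_perception: float = 0.25  # task-specific log-threshold jitter
    task_jitter_sd_tapping: float = 0.15  # task-specific log-cv jitter
    motor_noise_fraction: float = 0.2  # share of ITI variance from motor delays
    drift_fraction: float = 0.1  # unpaced: share of ITI variance from drift
    tap_artifact_rate: float = 0.02  # probability of a pad-bounce extra tap
    word_ms_mean: float = 750.0
    word_ms_sd: float = 40.0
    segment_props: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Onset": (0.18, 0.14), "Coda": (0.20, 0.15)}
    )  # condition → (cc, v) word-normalized baseline proportions
    prop_between_sd: float = 0.02  # between-participant SD of baseline proportions
    speech_noise_cv: float = 0.06  # within-participant trial-to-trial cv of proportions
    persistence: dict[str, float] = field(
        default_factory=lambda: {"Onset": 0.2, "Coda": 0.9}
    )  # after-effect carry-over: 1 = fully adaptive, 0 = purely online
    schedule: PhasePlan = PhasePlan()
    perception_tasks: tuple[PerceptionTaskSpec, ...] = field(
        default_factory=default_perception_tasks
    )
    tapping_tasks: tuple[TapTaskSpec, ...] = field(default_factory=default_tapping_tasks)
    n_catch: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        if not 0 <= self.mistrigger_rate < 1:
            raise ValueError("mistrigger_rate must lie in [0, 1)")
        corr = np.asarray(self.trait_correlations, dtype=float)
        if corr.shape != (len(TRAIT_NAMES),) * 2:
            raise ValueError("trait_correlations must be 4x4 over " + str(TRAIT_NAMES))
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError(
                f"trait correlation matrix must be symmetric with unit diagonal: {corr}"
            )
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError(
                f"trait correlation matrix is not positive semi-definite: {corr}"
            )
        for seg, slopes in self.effect_sizes.items():
            if seg not in SEGMENT_LABELS:
                raise ValueError(f"unknown segment label {seg!r} in effect_sizes")
            for trait in slopes:
                if trait not in TRAIT_NAMES:
                    raise ValueError(f"unknown trait {trait!r} in effect_sizes[{seg!r}]")


@dataclass
class CohortData:
    config: CohortConfig
    traits: list[TraitProfile]
    tap_series: dict[tuple[str, str], "object"]  # (participant_id, task) → TapSeries
    staircase_logs: dict[tuple[str, str], sc.StaircaseLog]
    segment_tables: pd.DataFrame  # long format over participants × conditions

    def participants(self) -> list[str]:
        return [t.participant_id for t in self.traits]

    # -- CSV bundle ----------------------------------------------------
    def taps_frame(self) -> pd.DataFrame:
        rows = [
            {"participant_id": pid, "task": task, "tap_time_ms": t}
            for (pid, task), series in self.tap_series.items()
            for t in series.tap_times_ms
        ]
        return pd.DataFrame(rows, columns=["participant_id", "task", "tap_time_ms"])

    def staircase_frame(self) -> pd.DataFrame:
        rows = []
        for (pid, task), log in self.staircase_logs.items():
            outcome_iter = iter(log.outcomes)
            pending = None
            for trial in log.trials:
                outcome = ""
                if not trial.is_catch:
                    if trial.correct and trial.attempt_position == "first":
                        pending = trial
                    else:
                        o = next(outcome_iter)
                        outcome = "success" if o.success else "failure"
                        pending = None
                rows.append(
                    {
                        "participant_id": pid,
                        "task": task,
                        "trial": trial.index,
                        "delta_ms": trial.delta_ms,
                        "is_catch": int(trial.is_catch),
                        "response": int(trial.response),
                        "outcome": outcome,
                    }
                )
            del pending
        return pd.DataFrame(
            rows,
            columns=[
                "participant_id", "task", "trial", "delta_ms",
                "is_catch", "response", "outcome",
            ],
        )

    def segments_frame(self) -> pd.DataFrame:
        return self.segment_tables.copy()

    def traits_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.traits:
            row = {
                "participant_id": t.participant_id,
                "acuity_general": t.acuity_general,
                "acuity_bat": t.acuity_bat,
                "motor_var_paced": t.motor_var_paced,
                "motor_var_unpaced": t.motor_var_unpaced,
                "lapse_rate": t.lapse_rate,
                "false_alarm_rate": t.false_alarm_rate,
            }
            row.update({f"comp_true_{seg}": t.compensation_true[seg] for seg in SEGMENT_LABELS})
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in [
            ("taps.csv", self.taps_frame()),
            ("staircase.csv", self.staircase_frame()),
            ("segments.csv", self.segments_frame()),
            ("traits.csv", self.traits_frame()),
        ]:
            path = out / name
            frame.to_csv(path, index=False)
            paths[name] = path
        return paths


# ---------------------------------------------------------------------------
# trait sampling
# ---------------------------------------------------------------------------

def draw_traits(config: CohortConfig, rng: np.random.Generator) -> list[TraitProfile]:
    """Sample correlated latent profiles and their planted compensations."""
    corr = np.asarray(config.trait_correlations, dtype=float)
    # eigen square root tolerates the PSD boundary (e.g. perfect correlation)
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    means = np.asarray(config.trait_means, dtype=float)
    sds = np.asarray(config.trait_sds, dtype=float)
    profiles = []
    for i in range(config.n_participants):
        z = root @ rng.standard_normal(len(TRAIT_NAMES))
        latent = means + sds * z
        # a trait with zero spread carries no standardized variation
        z_eff = np.where(sds > 0, z, 0.0)
        zmap = dict(zip(TRAIT_NAMES, z_eff))
        comp = {}
        for seg in SEGMENT_LABELS:
            slopes = config.effect_sizes.get(seg, {})
            lin = sum(beta * zmap[trait] for trait, beta in slopes.items())
            noise = rng.normal(0.0, config.noise_sd_compensation) if config.noise_sd_compensation else 0.0
            comp[seg] = config.compensation_means.get(seg, 0.0) + config.compensation_scale * lin + noise
        profiles.append(
            TraitProfile(
                participant_id=f"P{i + 1:03d}",
                acuity_general=float(latent[0]),
                acuity_bat=float(latent[1]),
                motor_var_paced=float(np.exp(latent[2])),
                motor_var_unpaced=float(np.exp(latent[3])),
                lapse_rate=config.lapse_rate,
                false_alarm_rate=config.false_alarm_rate,
                compensation_true=comp,
                latent_z={k: float(x) for k, x in zmap.items()},
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# psychophysical observer
# ---------------------------------------------------------------------------

def task_threshold(
    trait: TraitProfile,
    task: PerceptionTaskSpec,
    acuity_spread: float = 0.40,
    log_jitter: float = 0.0,
) -> float:
    """Trait-implied threshold for one task (ms); higher acuity → lower."""
    z = sum(w * trait.latent_z.get(name, 0.0) for name, w in task.loads.items())
    return float(task.theta_ref_ms * np.exp(-acuity_spread * z + log_jitter))


def simulate_response(
    trait: TraitProfile,
    task_kind: str,
    delta_ms: float,
    is_catch: bool,
    rng: np.random.Generator,
    *,
    theta_ms: float,
    slope: float = 0.15,
) -> bool:
    """One binary judgement (True = "different"/"misaligned").

    Non-catch: P(correct) = 0.5 + (0.5 − lapse)·F((ln δ − ln θ)/s) with a
    logistic F, so P(correct) = 0.75 − lapse/2 at δ = θ.  Catch trials
    are answered "same"/"aligned" with probability 1 − false_alarm_rate.
    Both task families are binary judgements at chance 0.5, so the same
    observer serves the 2I discrimination and 1I beat-alignment designs.
    """
    if delta_ms < 0:
        raise ValueError("delta must be non-negative")
    if task_kind not in ("discrimination", "beat_alignment"):
        raise ValueError(f"unknown task kind {task_kind!r}")
    if is_catch:
        return rng.random() < trait.false_alarm_rate
    if delta_ms == 0:
        p_correct = 0.5
    else:
        x = (math.log(delta_ms) - math.log(theta_ms)) / slope
        p_correct = 0.5 + (0.5 - trait.lapse_rate) / (1.0 + math.exp(-x))
    return rng.random() < p_correct


def make_responder(
    trait: TraitProfile,
    task: PerceptionTaskSpec,
    rng: np.random.Generator,
    *,
    acuity_spread: float = 0.40,
    slope: float = 0.15,
    log_jitter: float = 0.0,
) -> sc.Responder:
    theta = task_threshold(trait, task, acuity_spread, log_jitter)

    def responder(delta_ms: float, is_catch: bool) -> bool:
        return simulate_response(
            trait, task.kind, delta_ms, is_catch, rng, theta_ms=theta, slope=slope
        )

    return responder


# ---------------------------------------------------------------------------
# tapping
# ---------------------------------------------------------------------------

def simulate_tap_series(
    trait: TraitProfile,
    task: TapTaskSpec,
    rng: np.random.Generator,
    *,
    motor_noise_fraction: float = 0.2,
    drift_fraction: float = 0.1,
    artifact_rate: float = 0.0,
    cv_log_jitter: float = 0.0,
):
    """Two-level timing model: central intervals plus motor delays.

    ITI_n = C_n + M_{n+1} − M_n gives Var(ITI) = σc² + 2σm² and the
    lag-1 negative covariance (−σm²) typical of tapping.  The variance
    budget (cv·IOI)² is split so that 2σm² takes ``motor_noise_fraction``
    ·2 of it; unpaced tapping adds a reflected random walk on the
    central interval worth ``drift_fraction`` of the budget.  Pad
    bounces (extra taps 30–80 ms after a true tap) are injected at
    ``artifact_rate`` per tap to exercise artifact cleaning.
    """
    from .tapping import TapSeries

    paced = task.ioi_ms is not None
    if paced and task.ioi_ms <= 0:
        raise ValueError("IOI must be positive")
    if paced:
        ioi = float(task.ioi_ms)
        cv = trait.motor_var_paced
    else:
        # self-chosen tempo, stable within the series
        ioi = float(task.base_tempo_ms * np.exp(rng.normal(0.0, 0.10)))
        cv = trait.motor_var_unpaced
    cv = float(cv * np.exp(cv_log_jitter))
    n_taps = max(int(round(task.duration_s * 1000.0 / ioi)) + 1, 41)

    var_total = (cv * ioi) ** 2
    var_motor = motor_noise_fraction * var_total  # σm² ; contributes 2σm²
    var_drift = drift_fraction * var_total if not paced else 0.0
    var_central = var_total - 2.0 * var_motor - var_drift
    if var_central < 0:
        raise ValueError("variance budget infeasible; lower motor/drift fractions")

    n_iti = n_taps - 1
    central = ioi + math.sqrt(var_central) * rng.standard_normal(n_iti)
    if var_drift > 0:
        bound = math.sqrt(3.0 * var_drift)  # reflected walk ≈ uniform(−b, b)
        step = bound / 5.0
        walk = np.cumsum(step * rng.standard_normal(n_iti))
        walk = bound - np.abs((walk + bound) % (4 * bound) - 2 * bound)
        central = central + walk
    motor = math.sqrt(var_motor) * rng.standard_normal(n_taps)
    taps = np.concatenate([[0.0], np.cumsum(central)]) + motor
    taps = np.sort(taps)

    if artifact_rate > 0:
        bounce_at = rng.random(n_taps) < artifact_rate
        bounces = taps[bounce_at] + rng.uniform(30.0, 80.0, size=int(bounce_at.sum()))
        taps = np.sort(np.concatenate([taps, bounces]))
    # enforce strict monotonicity after noise/bounces
    eps = 1e-6
    for i in range(1, len(taps)):
        if taps[i] <= taps[i - 1]:
            taps[i] = taps[i - 1] + eps
    return TapSeries(
        participant_id=trait.participant_id,
        task=task.name,
        tap_times_ms=tuple(float(t) for t in taps),
        nominal_ioi_ms=task.ioi_ms,
    )


# ---------------------------------------------------------------------------
# perturbation trials
# ---------------------------------------------------------------------------

def simulate_perturbation_table(
    trait: TraitProfile,
    condition: str,
    schedule: PhasePlan,
    rng: np.random.Generator,
    *,
    config: CohortConfig,
) -> pd.DataFrame:
    """Per-trial segment durations for one participant and condition.

    Baseline word-normalized proportions carry participant-level offsets
    and trial-to-trial noise; during the ramp the planted compensation
    builds linearly to its hold-phase value; the after-effect phase
    retains ``persistence`` of it.  Ramp/hold trials are flagged
    perturbation-invalid with probability ``mistrigger_rate``.
    """
    if condition not in ("Onset", "Coda"):
        raise ValueError(f"condition must be Onset or Coda, got {condition!r}")
    cc_label = "OnsetCC" if condition == "Onset" else "CodaCC"
    v_label = "OnsetV" if condition == "Onset" else "CodaV"
    # planted percent change of the produced normalized duration
    raw_shift = {
        "cc": SEGMENT_SPEC[cc_label][2] * trait.compensation_true[cc_label],
        "v": SEGMENT_SPEC[v_label][2] * trait.compensation_true[v_label],
    }
    cc0, v0 = config.segment_props[condition]
    cc0 = cc0 + rng.normal(0.0, config.prop_between_sd)
    v0 = v0 + rng.normal(0.0, config.prop_between_sd)
    persistence = config.persistence[condition]

    rows = []
    trial = 0
    for phase, length in schedule.phases:
        for k in range(length):
            trial += 1
            if phase == "baseline":
                level = 0.0
            elif phase == "ramp":
                level = (k + 1) / length
            elif phase == "hold":
                level = 1.0
            else:
                level = persistence
            word = rng.normal(config.word_ms_mean, config.word_ms_sd)
            word = max(word, 200.0)
            cc_prop = cc0 * (1.0 + level * raw_shift["cc"] / 100.0)
            v_prop = v0 * (1.0 + level * raw_shift["v"] / 100.0)
            cc_prop *= 1.0 + config.speech_noise_cv * rng.standard_normal()
            v_prop *= 1.0 + config.speech_noise_cv * rng.standard_normal()
            cc_prop = float(np.clip(cc_prop, 0.01, 0.45))
            v_prop = float(np.clip(v_prop, 0.01, 0.45))
            valid = True
            if phase in ("ramp", "hold"):
                valid = bool(rng.random() >= config.mistrigger_rate)
            rows.append(
                {
                    "participant_id": trait.participant_id,
                    "condition": condition,
                    "trial": trial,
                    "phase": phase,
                    "word_ms": round(word, 3),
                    "cc_ms": round(cc_prop * word, 3),
                    "v_ms": round(v_prop * word, 3),
                    "pert_valid": int(valid),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> CohortData:
    """Generate all observables for all participants, optionally writing CSVs.

    One master seed drives everything through per-participant,
    per-bundle child streams (``SeedSequence.spawn``), so regeneration
    with the same config is bit-identical.
    """
    master = np.random.SeedSequence(config.seed)
    trait_ss, obs_ss = master.spawn(2)
    traits = draw_traits(config, np.random.default_rng(trait_ss))

    tap_series: dict[tuple[str, str], object] = {}
    logs: dict[tuple[str, str], sc.StaircaseLog] = {}
    seg_frames = []
    for trait, pss in zip(traits, obs_ss.spawn(len(traits))):
        stair_ss, tap_ss, seg_ss, jitter_ss = pss.spawn(4)
        jit_rng = np.random.default_rng(jitter_ss)
        for task, tss in zip(config.perception_tasks, stair_ss.spawn(len(config.perception_tasks))):
            rng = np.random.default_rng(tss)
            jitter = jit_rng.normal(0.0, config.task_jitter_sd_perception)
            responder = make_responder(
                trait, task, rng,
                acuity_spread=config.acuity_spread,
                slope=config.psychometric_slope,
                log_jitter=jitter,
            )
            cfg = sc.StaircaseConfig(
                start_delta_ms=task.start_delta_ms,
                stop_reversals=task.stop_reversals,
                n_catch=config.n_catch,
            )
            logs[(trait.participant_id, task.name)] = sc.run_staircase(responder, cfg, rng)
        for task, tss in zip(config.tapping_tasks, tap_ss.spawn(len(config.tapping_tasks))):
            rng = np.random.default_rng(tss)
            jitter = jit_rng.normal(0.0, config.task_jitter_sd_tapping)
            tap_series[(trait.participant_id, task.name)] = simulate_tap_series(
                trait, task, rng,
                motor_noise_fraction=config.motor_noise_fraction,
                drift_fraction=config.drift_fraction,
                artifact_rate=config.tap_artifact_rate,
                cv_log_jitter=jitter,
            )
        for condition, css in zip(("Onset", "Coda"), seg_ss.spawn(2)):
            rng = np.random.default_rng(css)
            seg_frames.append(
                simulate_perturbation_table(
                    trait, condition, config.schedule, rng, config=config
                )
            )

    data = CohortData(
        config=config,
        traits=traits,
        tap_series=tap_series,
        staircase_logs=logs,
        segment_tables=pd.concat(seg_frames, ignore_index=True),
    )
    if out_dir is not None:
        data.write_csv(out_dir)
    return data


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    return replace(config, seed=int(seed))
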