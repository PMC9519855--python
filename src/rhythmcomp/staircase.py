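"""Adaptive 2-down/1-up staircases with multiplicative steps.

The procedure estimates a listener's differential threshold (*acuity
score*) for a temporal manipulation.  Stimulus pairs differ by a *delta*
(ms).  A pair is re-presented after one correct identification; two
correct responses in a row at the same delta complete a *success* and
halve the delta, a single incorrect response completes a *failure* and
multiplies the delta by 1.5.  Deltas are rounded to a resolution (1 ms),
floored and capped.  A *reversal* is counted whenever the outcome
quality (success/failure) changes; the run stops at a fixed number of
reversals.  Catch trials (delta 0) are interleaved to detect guessing;
they never touch the delta track.

The acuity score is the mean delta of the most stable window of six
consecutive reversals (lowest sample SD, earliest window on ties).  A
run is valid when more than half of the catch trials were answered
correctly and the score fell below 70% of the start delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseTrial",
    "Outcome",
    "StaircaseLog",
    "ThresholdEstimate",
    "ValidityReport",
    "Staircase",
    "advance",
    "count_reversals",
    "run_staircase",
    "estimate_threshold",
    "check_validity",
]


class StaircaseError(RuntimeError):
    """Raised for protocol violations (advancing a finished run, divergence)."""


@dataclass(frozen=True)
class StaircaseConfig:
    start_delta_ms: float
    step_down_factor: float = 0.5
    step_up_factor: float = 1.5
    stop_reversals: int = 12
    n_catch: int = 5
    delta_resolution_ms: float = 1.0
    delta_floor_ms: float = 1.0
    delta_cap_ms: float | None = None  # defaults to start delta
    stable_window: int = 6
    max_trials: int = 1000
    catch_horizon: int = 35  # attempt slots over which catches are scattered

    def __post_init__(self) -> None:
        if not (0 < self.step_down_factor < 1 < self.step_up_factor):
            raise ValueError(
                "step factors must satisfy 0 < down < 1 < up, got "
                f"{self.step_down_factor}, {self.step_up_factor}"
            )
        if self.stop_reversals < self.stable_window + 1:
            raise ValueError("stop_reversals must exceed stable_window")
        if self.cap_ms < self.delta_floor_ms:
            raise ValueError("delta cap below floor")
        if self.start_delta_ms <= 0:
            raise ValueError("start delta must be positive")
        if not 0 <= self.n_catch:
            raise ValueError("n_catch must be non-negative")

    @property
    def cap_ms(self) -> float:
        return self.start_delta_ms if self.delta_cap_ms is None else self.delta_cap_ms

    def clip_round(self, delta: float) -> float:
        res = self.delta_resolution_ms
        delta = res * round(delta / res)
        return float(min(self.cap_ms, max(self.delta_floor_ms, delta)))


@dataclass(frozen=True)
class StaircaseTrial:
    index: int
    delta_ms: float
    is_catch: bool
    response: bool  # True = "different"/"misaligned"
    correct: bool
    attempt_position: str  # "first" or "second"


@dataclass(frozen=True)
class Outcome:
    success: bool
    delta_ms: float


@dataclass
class StaircaseLog:
    config: StaircaseConfig
    trials: list[StaircaseTrial] = field(default_factory=list)
    outcomes: list[Outcome] = field(default_factory=list)
    reversal_deltas: list[float] = field(default_factory=list)
    n_catch_presented: int = 0
    n_catch_correct: int = 0

    @property
    def terminated(self) -> bool:
        return len(self.reversal_deltas) >= self.config.stop_reversals


@dataclass(frozen=True)
class ThresholdEstimate:
    acuity_score_ms: float
    window_start_reversal: int
    window_sd_ms: float


@dataclass(frozen=True)
class ValidityReport:
    catch_correct_fraction: float
    score_below_70pct_start: bool
    valid: bool


class Staircase:
    """Mutable staircase state: feeds trials in, yields the next delta.

    Catch trials are the caller's concern (see :func:`run_staircase`);
    this class only tracks the delta staircase proper.
    """

    def __init__(self, config: StaircaseConfig):
        self.log = StaircaseLog(config=config)
        self.delta = float(config.start_delta_ms)
        self.pending_correct = False  # first correct response of an attempt seen

    @property
    def terminated(self) -> bool:
        return self.log.terminated

    def advance(self, trial: StaircaseTrial) -> float:
        """Record a completed non-catch trial; return the next delta.

        After the first correct response of an attempt the same delta is
        re-presented.  On a completed outcome the delta is multiplied by
        the step factor, rounded to the resolution and clipped.
        """
        if self.terminated:
            raise StaircaseError("cannot advance a terminated staircase")
        if trial.is_catch:
            raise StaircaseError("catch trials do not advance the staircase")
        self.log.trials.append(trial)
        if trial.correct and not self.pending_correct:
            self.pending_correct = True
            return self.delta  # re-present the same pair
        success = trial.correct
        self.pending_correct = False
        self._complete(Outcome(success=success, delta_ms=self.delta))
        cfg = self.log.config
        factor = cfg.step_down_factor if success else cfg.step_up_factor
        self.delta = cfg.clip_round(self.delta * factor)
        return self.delta

    def _complete(self, outcome: Outcome) -> None:
        outcomes = self.log.outcomes
        if outcomes and outcomes[-1].success != outcome.success:
            self.log.reversal_deltas.append(outcome.delta_ms)
        outcomes.append(outcome)


def advance(state: Staircase, trial: StaircaseTrial) -> Staircase:
    """Functional wrapper over :meth:`Staircase.advance` (mutates and returns)."""
    state.advance(trial)
    return state


def count_reversals(outcomes: Sequence[Outcome]) -> list[tuple[int, float]]:
    """Return (position, delta) for each reversal in an outcome sequence.

    A reversal is an outcome whose success flag differs from the
    immediately preceding outcome's; the delta recorded is the delta at
    which the changed outcome completed.  Positions are 1-based.
    """
    if not outcomes:
        raise ValueError("outcomes must be nonempty")
    return [
        (i + 1, o.delta_ms)
        for i, o in enumerate(outcomes)
        if i > 0 and o.success != outcomes[i - 1].success
    ]


Responder = Callable[[float, bool], bool]


def run_staircase(
    responder: Responder,
    config: StaircaseConfig,
    rng: np.random.Generator,
) -> StaircaseLog:
    """Run one adaptive staircase against a response callback.

    ``responder(delta_ms, is_catch)`` returns the binary judgement
    (True = "different"/"misaligned").  On non-catch trials a True
    response is correct; on catch trials a False response is correct.
    Catch trials are placed at uniformly random attempt slots within the
    first ``config.catch_horizon`` attempts and never affect the delta
    track or reversal bookkeeping; slots beyond termination are simply
    not presented.
    """
    stair = Staircase(config)
    catch_slots = sorted(
        rng.choice(config.catch_horizon, size=config.n_catch, replace=False)
    ) if config.n_catch else []
    attempt = 0
    trial_index = 0

    def present_catches() -> None:
        nonlocal trial_index
        log = stair.log
        while catch_slots and catch_slots[0] == attempt:
            catch_slots.pop(0)
            response = bool(responder(0.0, True))
            correct = not response
            trial_index += 1
            log.trials.append(
                StaircaseTrial(trial_index, 0.0, True, response, correct, "first")
            )
            log.n_catch_presented += 1
            log.n_catch_correct += int(correct)

    while not stair.terminated:
        present_catches()
        attempt += 1
        position = "second" if stair.pending_correct else "first"
        if position == "first" and len(stair.log.trials) >= config.max_trials:
            raise StaircaseError(
                f"staircase exceeded max_trials={config.max_trials} without "
                f"reaching {config.stop_reversals} reversals"
            )
        response = bool(responder(stair.delta, False))
        trial_index += 1
        stair.advance(
            StaircaseTrial(trial_index, stair.delta, False, response, response, position)
        )
    return stair.log


def estimate_threshold(log: StaircaseLog) -> ThresholdEstimate:
    """Mean delta of the most stable (lowest-SD) six-reversal window.

    All windows of ``stable_window`` consecutive reversal deltas are
    scanned; the window with the smallest sample SD wins, earliest
    window on ties.
    """
    w = log.config.stable_window
    revs = np.asarray(log.reversal_deltas, dtype=float)
    if len(revs) < w:
        raise ValueError(f"need at least {w} reversals, got {len(revs)}")
    best_i, best_sd = 0, np.inf
    for i in range(len(revs) - w + 1):
        sd = float(np.std(revs[i : i + w], ddof=1))
        if sd < best_sd:
            best_i, best_sd = i, sd
    return ThresholdEstimate(
        acuity_score_ms=float(np.mean(revs[best_i : best_i + w])),
        window_start_reversal=best_i + 1,
        window_sd_ms=best_sd,
    )


def check_validity(log: StaircaseLog, estimate: ThresholdEstimate) -> ValidityReport:
    """Catch-trial and score gates flagging chance-level responders."""
    frac = (
        log.n_catch_correct / log.n_catch_presented if log.n_catch_presented else 1.0
    )
    below = estimate.acuity_score_ms < 0.7 * log.config.start_delta_ms
    return ValidityReport(
        catch_correct_fraction=frac,
        score_below_70pct_start=below,
        valid=(frac > 0.5) and below,
    )
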