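"""Cleaning and summary statistics for finger-tapping series.

A tap series is reduced to inter-tap intervals (ITIs): the first ten
taps are discarded, ITIs under 100 ms are removed as artifacts (pad
bounces), and ITIs outside mean ± 3 SD (bounds computed once on the
artifact-free intervals) are removed as outliers.  The summary is the
mean ITI and its coefficient of variation (SD/mean), the study's motor
variability measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TapSeries",
    "CleaningParams",
    "ITISeries",
    "TappingSummary",
    "clean_itis",
    "summarize",
]


@dataclass(frozen=True)
class TapSeries:
    participant_id: str
    task: str
    tap_times_ms: tuple[float, ...]
    nominal_ioi_ms: float | None = None  # None for unpaced ("free") tapping

    def __post_init__(self) -> None:
        t = np.asarray(self.tap_times_ms, dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"tap times must be strictly increasing ({self.participant_id}, {self.task})"
            )


@dataclass(frozen=True)
class CleaningParams:
    discard_first_taps: int = 10
    artifact_max_ms: float = 100.0
    outlier_sd: float = 3.0


@dataclass(frozen=True)
class ITISeries:
    itis_ms: tuple[float, ...]
    n_removed_artifact: int
    n_removed_outlier: int


@dataclass(frozen=True)
class TappingSummary:
    mean_iti_ms: float
    cv_iti: float


def clean_itis(series: TapSeries, params: CleaningParams = CleaningParams()) -> ITISeries:
    """Discard warm-up taps, then artifact and outlier ITIs.

    Outlier bounds are computed in a single pass on the artifact-free
    intervals, so cleaning an already-clean series removes nothing
    further.
    """
    taps = np.asarray(series.tap_times_ms, dtype=float)
    if len(taps) < params.discard_first_taps + 2:
        raise ValueError(
            f"need at least {params.discard_first_taps + 2} taps, got {len(taps)}"
        )
    itis = np.diff(taps[params.discard_first_taps :])
    keep = itis >= params.artifact_max_ms
    n_artifact = int((~keep).sum())
    itis = itis[keep]
    n_outlier = 0
    if len(itis) >= 2:
        mean, sd = itis.mean(), itis.std(ddof=1)
        lo, hi = mean - params.outlier_sd * sd, mean + params.outlier_sd * sd
        inside = (itis >= lo) & (itis <= hi)
        n_outlier = int((~inside).sum())
        itis = itis[inside]
    return ITISeries(tuple(itis), n_artifact, n_outlier)


def summarize(itis: ITISeries) -> TappingSummary:
    x = np.asarray(itis.itis_ms, dtype=float)
    if len(x) < 2:
        raise ValueError(f"need at least 2 retained ITIs, got {len(x)}")
    mean = float(x.mean())
    return TappingSummary(mean_iti_ms=mean, cv_iti=float(x.std(ddof=1) / mean))
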