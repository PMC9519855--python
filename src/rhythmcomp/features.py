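"""Feature screening and reduction for the task batteries.

The perception battery (five acuity thresholds) and the paced-tapping
battery (eight cv values) are screened with the Kaiser–Meyer–Olkin
measure of sampling adequacy, sparse missingness is filled by k-nearest
neighbour imputation, and each battery is reduced by PCA on the
correlation matrix with Kaiser (eigenvalue > 1) retention.  Unpaced
tapping variability is kept as its own z-normalized predictor.  Values
outside the 95% normal interval (mean ± 1.96 SD) of a measure are
treated as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd

__all__ = [
    "MSAReport",
    "PCAResult",
    "ReducedFeatures",
    "kmo",
    "knn_impute",
    "pca_reduce",
    "loading_cutoff",
    "ci_outlier_mask",
    "assemble_predictors",
]

PREDICTOR_COLUMNS = (
    "pc1_auditory_acuity",
    "pc2_bat_perception",
    "pc1_paced_motor_var",
    "unpaced_motor_var_z",
)


@dataclass(frozen=True)
class MSAReport:
    overall_msa: float
    per_task_msa: dict[str, float]
    excluded_tasks: tuple[str, ...]

    @property
    def admissible(self) -> bool:
        return self.overall_msa > 0.5


@dataclass(frozen=True)
class PCAResult:
    tasks: tuple[str, ...]
    eigenvalues: np.ndarray  # descending, sums to n_tasks
    loadings: np.ndarray  # tasks × components (all of them)
    scores: pd.DataFrame  # participants × retained components
    retained: int

    def flagged_loadings(self) -> dict[str, list[str]]:
        """Tasks whose |loading| exceeds the equal-contribution cutoff."""
        cut = loading_cutoff(len(self.tasks))
        out = {}
        for c in range(self.retained):
            out[f"PC{c + 1}"] = [
                t for t, l in zip(self.tasks, self.loadings[:, c]) if abs(l) > cut
            ]
        return out


@dataclass
class ReducedFeatures:
    predictors: pd.DataFrame  # participants × PREDICTOR_COLUMNS
    outlier_flags: pd.DataFrame  # same shape, True where value was removed
    imputed_flags: pd.DataFrame  # same shape, True where value was imputed
    excluded_participants: list[str] = field(default_factory=list)


def kmo(correlations: pd.DataFrame | np.ndarray, *, max_cond: float = 1e10,
        ridge: float = 1e-8) -> MSAReport:
    """Kaiser–Meyer–Olkin sampling adequacy from a task correlation matrix.

    Partial correlations come from the inverse correlation matrix
    (u_ij = −inv_ij/√(inv_ii·inv_jj)); per-task MSA_j = Σ_{i≠j} r²_ij /
    (Σ_{i≠j} r²_ij + Σ_{i≠j} u²_ij) and the overall MSA pools all
    off-diagonal pairs.  A ridge is added to the diagonal only when the
    matrix is near-singular (condition number above ``max_cond``).
    """
    if isinstance(correlations, pd.DataFrame):
        tasks = tuple(str(c) for c in correlations.columns)
        R = correlations.to_numpy(dtype=float)
    else:
        R = np.asarray(correlations, dtype=float)
        tasks = tuple(f"task{i + 1}" for i in range(R.shape[0]))
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > max_cond:
        R = R + ridge * np.eye(len(R))
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular correlation matrix; consider ridge regularization"
        ) from err
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(len(R), dtype=bool)
    r2 = np.where(off, R**2, 0.0)
    u2 = np.where(off, partial**2, 0.0)
    per_task = r2.sum(axis=1) / (r2.sum(axis=1) + u2.sum(axis=1))
    overall = r2.sum() / (r2.sum() + u2.sum())
    excluded = tuple(t for t, m in zip(tasks, per_task) if m < 0.5)
    return MSAReport(
        overall_msa=float(overall),
        per_task_msa={t: float(m) for t, m in zip(tasks, per_task)},
        excluded_tasks=excluded,
    )


def knn_impute(X: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing cells with the mean of the k nearest rows.

    Distances are Euclidean over the z-scaled columns observed in both
    rows (scaled by the number of shared columns so rows with different
    missingness patterns are comparable); a neighbour must have the
    target column observed.
    """
    df = X.copy().astype(float)
    complete = df.dropna()
    if complete.empty:
        raise ValueError("knn imputation needs at least one complete row")
    if k > len(complete):
        raise ValueError(f"k={k} exceeds the {len(complete)} complete rows")
    mu, sd = df.mean(), df.std(ddof=1).replace(0.0, 1.0)
    Z = (df - mu) / sd
    zvals = Z.to_numpy()
    for i, row in enumerate(zvals):
        miss = np.isnan(row)
        if not miss.any():
            continue
        for j in np.flatnonzero(miss):
            donors = ~np.isnan(zvals[:, j])
            donors[i] = False
            dists = []
            for r in np.flatnonzero(donors):
                shared = ~np.isnan(row) & ~np.isnan(zvals[r])
                if not shared.any():
                    continue
                d2 = np.mean((row[shared] - zvals[r][shared]) ** 2)
                dists.append((sqrt(d2), r))
            if len(dists) < k:
                raise ValueError("not enough donor rows for imputation")
            dists.sort(key=lambda t: t[0])
            nearest = [r for _, r in dists[:k]]
            df.iloc[i, j] = df.iloc[nearest, j].mean()
    return df


def pca_reduce(
    X: pd.DataFrame,
    *,
    orient: str = "negative",
    score_components: int | None = None,
) -> PCAResult:
    """PCA on the correlation matrix with Kaiser retention.

    Values are centered and scaled (correlation PCA), so the result is
    invariant to rescaling any task column.  Components with eigenvalue
    > 1 are retained; each component is sign-oriented so the sum of its
    loadings is ≤ 0 (``orient="negative"``, perception convention: a
    higher score means lower thresholds, i.e. better perception) or ≥ 0
    (``orient="positive"``, tapping convention).  ``score_components``
    forces scores for at least that many leading components even when
    Kaiser retains fewer (the ``retained`` count still reports the
    Kaiser criterion).
    """
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 tasks")
    if X.isna().any().any():
        raise ValueError("PCA input must be complete; impute first")
    sd = X.std(ddof=1)
    dead = sd[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance task(s): {list(dead.index)}")
    Z = (X - X.mean()) / sd
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    w, v = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for c in range(v.shape[1]):
        s = v[:, c].sum()
        if (orient == "negative" and s > 0) or (orient == "positive" and s < 0):
            v[:, c] = -v[:, c]
    retained = int((w > 1.0).sum())
    retained = max(retained, 1)
    n_scores = max(retained, score_components or 0)
    n_scores = min(n_scores, X.shape[1])
    scores = Z.to_numpy() @ v[:, :n_scores]
    score_df = pd.DataFrame(
        scores, index=X.index, columns=[f"PC{i + 1}" for i in range(n_scores)]
    )
    return PCAResult(
        tasks=tuple(str(c) for c in X.columns),
        eigenvalues=w,
        loadings=v,
        scores=score_df,
        retained=retained,
    )


def loading_cutoff(n_tasks: int) -> float:
    """Equal-contribution loading threshold, √(1/n_tasks)."""
    if n_tasks < 1:
        raise ValueError("n_tasks must be at least 1")
    return sqrt(1.0 / n_tasks)


def ci_outlier_mask(values: pd.Series | np.ndarray, *, z: float = 1.96) -> np.ndarray:
    """True for values to retain; strict mean ± z·SD rule, NaNs retained."""
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if len(obs) < 3:
        raise ValueError("need at least 3 values")
    sd = obs.std(ddof=1)
    if sd == 0:
        return np.ones_like(x, dtype=bool)
    lo, hi = obs.mean() - z * sd, obs.mean() + z * sd
    keep = np.ones_like(x, dtype=bool)
    with np.errstate(invalid="ignore"):
        keep[~np.isnan(x)] = (x[~np.isnan(x)] > lo) & (x[~np.isnan(x)] < hi)
    return keep


def assemble_predictors(
    perception_pca: PCAResult,
    tapping_pca: PCAResult,
    unpaced: pd.Series,
    *,
    k: int = 5,
    outlier_z: float = 1.96,
) -> ReducedFeatures:
    """Combine the retained components and unpaced variability.

    Keeps perception PC1/PC2, tapping PC1, and the z-normalized unpaced
    cv; removes per-measure 95%-CI outliers; excludes participants with
    more than one missing predictor and knn-imputes single holes.
    Response (compensation) variables are never touched here.
    """
    perception = perception_pca.scores
    if perception.shape[1] < 2:
        raise ValueError("perception PCA must provide at least 2 components")
    idx = perception.index
    idx = idx.intersection(tapping_pca.scores.index).intersection(unpaced.index)
    unpaced = unpaced.loc[idx].astype(float)
    z_unpaced = (unpaced - unpaced.mean()) / unpaced.std(ddof=1)
    df = pd.DataFrame(
        {
            "pc1_auditory_acuity": perception.loc[idx, "PC1"],
            "pc2_bat_perception": perception.loc[idx, "PC2"],
            "pc1_paced_motor_var": tapping_pca.scores.loc[idx, "PC1"],
            "unpaced_motor_var_z": z_unpaced,
        }
    )
    flags = pd.DataFrame(False, index=df.index, columns=df.columns)
    for col in df.columns:
        keep = ci_outlier_mask(df[col], z=outlier_z)
        flags[col] = ~keep
        df.loc[~keep, col] = np.nan
    n_missing = df.isna().sum(axis=1)
    excluded = list(df.index[n_missing > 1])
    df = df[n_missing <= 1]
    flags = flags.loc[df.index]
    imputed = df.isna()
    if df.isna().any().any():
        df = knn_impute(df, k=min(k, len(df.dropna())))
    return ReducedFeatures(
        predictors=df,
        outlier_flags=flags,
        imputed_flags=imputed,
        excluded_participants=excluded,
    )
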