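"""Regression trees and confirmatory linear models.

The tree is a CART-style least-squares tree: every predictor and every
midpoint between consecutive sorted unique values is scanned, the split
minimizing the summed child SSE wins (ties: lower predictor index, then
lower threshold), subject to ``minbucket`` on both children.  A split is
kept only if it lowers the total SSE by at least ``cp`` times the root
SSE; ``prune="cv"`` additionally discards the whole tree when it fails
to beat the root mean on repeated 10-fold cross-validation, which is
how small-sample null data is protected against maximally selected
spurious splits.

The confirmatory model is an ordinary least-squares fit on the
predictors the tree selected, optionally with their pairwise
interactions, reported with coefficient t/p values, the overall F test,
R² and adjusted R².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TreeParams",
    "TreeNode",
    "TreeModel",
    "OLSFit",
    "best_split",
    "grow_tree",
    "predict_tree",
    "cv_error",
    "fit_ols",
]


@dataclass(frozen=True)
class TreeParams:
    minsplit: int = 4
    minbucket: int = 4
    cp: float = 0.1
    cv_folds: int = 10
    cv_reps: int = 3
    seed: int = 0
    allow_repeated_predictors: bool = True
    prune: str = "none"  # "none" (per-split cp gate only) or "cv"

    def __post_init__(self) -> None:
        if self.minbucket > self.minsplit:
            raise ValueError("minbucket must not exceed minsplit")
        if not 0 <= self.cp <= 1:
            raise ValueError("cp must lie in [0, 1]")
        if self.prune not in ("none", "cv"):
            raise ValueError("prune must be 'none' or 'cv'")


@dataclass
class TreeNode:
    n: int
    mean_response: float
    sse: float
    split_variable: str | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "mean_response": self.mean_response, "sse": self.sse}
        if not self.is_leaf:
            d.update(
                split_variable=self.split_variable,
                split_threshold=self.split_threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


@dataclass
class TreeModel:
    root: TreeNode
    feature_names: tuple[str, ...]
    params: TreeParams

    @property
    def n_splits(self) -> int:
        def count(node: TreeNode) -> int:
            return 0 if node.is_leaf else 1 + count(node.left) + count(node.right)

        return count(self.root)

    @property
    def first_split_variable(self) -> str | None:
        return self.root.split_variable

    def selected_predictors(self) -> list[str]:
        """Distinct split variables in first-use order (root first)."""
        seen: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            if node.split_variable not in seen:
                seen.append(node.split_variable)
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return seen

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"features": list(self.feature_names), "tree": self.root.to_dict()},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass(frozen=True)
class OLSFit:
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    f_statistic: float
    f_df: tuple[int, int]
    f_pvalue: float
    r2: float
    adj_r2: float
    n: int

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "t_values": self.t_values,
            "p_values": self.p_values,
            "f_statistic": self.f_statistic,
            "f_df": list(self.f_df),
            "f_pvalue": self.f_pvalue,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n": self.n,
        }


def _sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if len(y) else 0.0


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    minbucket: int,
    allowed: Sequence[int] | None = None,
) -> tuple[int, float, float] | None:
    """Exhaustive least-squares split search.

    Returns ``(predictor_index, threshold, sse_reduction)`` for the
    admissible split with the largest SSE reduction, or None.  Ties go
    to the lower predictor index, then the lower threshold.  Thresholds
    are midpoints of consecutive distinct sorted values; ``x <
    threshold`` routes left.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        return None
    total = y.sum()
    sse_parent = _sse(y)
    best: tuple[int, float, float] | None = None
    cols = range(X.shape[1]) if allowed is None else allowed
    for j in cols:
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        csum = np.cumsum(ys)
        k = np.arange(1, n)
        with np.errstate(invalid="ignore"):
            reduction = (
                csum[:-1] ** 2 / k + (total - csum[:-1]) ** 2 / (n - k) - total**2 / n
            )
        ok = (k >= minbucket) & ((n - k) >= minbucket) & (xs[:-1] < xs[1:])
        if not ok.any():
            continue
        reduction = np.where(ok, reduction, -np.inf)
        i = int(np.argmax(reduction))  # first max → lowest threshold on ties
        red = float(reduction[i])
        if red <= 1e-12 * max(sse_parent, 1.0):
            continue
        if best is None or red > best[2] + 1e-12:
            best = (j, float((xs[i] + xs[i + 1]) / 2.0), red)
    return best


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    params: TreeParams,
    root_sse: float,
    names: tuple[str, ...],
    used: frozenset[int],
) -> TreeNode:
    node = TreeNode(n=len(y), mean_response=float(y.mean()), sse=_sse(y))
    if node.n < params.minsplit or node.n < 2 * params.minbucket or node.sse <= 0:
        return node
    allowed = None
    if not params.allow_repeated_predictors:
        allowed = [j for j in range(X.shape[1]) if j not in used]
        if not allowed:
            return node
    found = best_split(X, y, params.minbucket, allowed)
    if found is None or found[2] < params.cp * root_sse:
        return node
    j, thr, _ = found
    mask = X[:, j] < thr
    child_used = used | {j}
    node.split_variable = names[j]
    node.split_threshold = thr
    node.left = _grow(X[mask], y[mask], params, root_sse, names, child_used)
    node.right = _grow(X[~mask], y[~mask], params, root_sse, names, child_used)
    return node


def grow_tree(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    params: TreeParams = TreeParams(),
) -> TreeModel:
    """Recursive least-squares partitioning with a cost-complexity gate.

    Each accepted split must reduce the total SSE by at least
    ``params.cp`` × SSE(root).  With ``params.prune == "cv"`` the grown
    tree is replaced by the root when it does not beat the root mean on
    repeated k-fold cross-validation (see :func:`cv_error`).
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(str(c) for c in X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = tuple(f"x{i + 1}" for i in range(Xv.shape[1]))
    yv = np.asarray(y, dtype=float)
    if len(yv) == 0:
        raise ValueError("empty data")
    root = _grow(Xv, yv, params, _sse(yv), names, frozenset())
    model = TreeModel(root=root, feature_names=names, params=params)
    if params.prune == "cv" and not root.is_leaf:
        grow_params = replace(params, prune="none")
        rel = cv_error(Xv, yv, grow_params, params.seed)
        if rel >= 1.0:
            model = TreeModel(
                root=TreeNode(n=len(yv), mean_response=float(yv.mean()), sse=_sse(yv)),
                feature_names=names,
                params=params,
            )
    return model


def _predict_node(node: TreeNode, row: dict[str, float]) -> float:
    while not node.is_leaf:
        if node.split_variable not in row or np.isnan(row[node.split_variable]):
            raise ValueError(f"missing split variable {node.split_variable!r}")
        node = node.left if row[node.split_variable] < node.split_threshold else node.right
    return node.mean_response


def predict_tree(model: TreeModel, x) -> np.ndarray | float:
    """Route rows through the tree; ``value < threshold`` goes left."""
    if isinstance(x, pd.DataFrame):
        cols = x.rename(columns=str)
        missing = [n for n in model.feature_names if n not in cols.columns]
        if missing:
            raise ValueError(f"missing split variable(s) {missing}")
        arr = cols[list(model.feature_names)].to_numpy(dtype=float)
        return np.array(
            [_predict_node(model.root, dict(zip(model.feature_names, row))) for row in arr]
        )
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return _predict_node(model.root, dict(zip(model.feature_names, x)))
    return np.array(
        [_predict_node(model.root, dict(zip(model.feature_names, row))) for row in x]
    )


def cv_error(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    params: TreeParams = TreeParams(),
    seed: int | None = None,
) -> float:
    """Cross-validated relative error: held-out SSE / root SSE.

    Seeded random fold assignment (uniform permutation chunked into
    ``cv_folds`` folds), averaged over ``cv_reps`` repetitions; values
    below 1 mean the tree generalizes better than the grand mean.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    names = (
        tuple(str(c) for c in X.columns)
        if isinstance(X, pd.DataFrame)
        else tuple(f"x{i + 1}" for i in range(Xv.shape[1]))
    )
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < params.cv_folds:
        raise ValueError(
            f"n={n} below cv_folds={params.cv_folds}; use fewer folds"
        )
    rng = np.random.default_rng(params.seed if seed is None else seed)
    grow_params = replace(params, prune="none")
    held_out = 0.0
    for _ in range(max(params.cv_reps, 1)):
        perm = rng.permutation(n)
        for fold in np.array_split(perm, params.cv_folds):
            train = np.setdiff1d(perm, fold)
            sub = grow_tree(
                pd.DataFrame(Xv[train], columns=names), yv[train], grow_params
            )
            pred = predict_tree(sub, Xv[fold])
            held_out += float(np.sum((yv[fold] - pred) ** 2))
    held_out /= max(params.cv_reps, 1)
    return held_out / _sse(yv)


def fit_ols(
    X: pd.DataFrame,
    y: Sequence[float],
    include_interactions: bool = True,
) -> OLSFit:
    """OLS with intercept; interactions are elementwise products.

    Reports per-coefficient SE/t/p, the overall F statistic with
    (p, n − p − 1) degrees of freedom, R² and adjusted R².
    """
    X = X.astype(float).copy()
    base = list(X.columns)
    if include_interactions and len(base) >= 2:
        for i in range(len(base)):
            for j in range(i + 1, len(base)):
                X[f"{base[i]}:{base[j]}"] = X[base[i]] * X[base[j]]
    yv = np.asarray(y, dtype=float)
    if len(yv) <= X.shape[1] + 1:
        raise ValueError("need n > number of terms + 1")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name columns adding no rank beyond the preceding ones
        collinear = []
        cols = design.columns.tolist()
        for stop in range(2, len(cols) + 1):
            if np.linalg.matrix_rank(design[cols[:stop]].to_numpy()) < stop - len(collinear):
                collinear.append(cols[stop - 1])
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    fit = sm.OLS(yv, design).fit()
    terms = tuple(design.columns)
    return OLSFit(
        terms=terms,
        coefficients={t: float(c) for t, c in zip(terms, fit.params)},
        std_errors={t: float(s) for t, s in zip(terms, fit.bse)},
        t_values={t: float(v) for t, v in zip(terms, fit.tvalues)},
        p_values={t: float(p) for t, p in zip(terms, fit.pvalues)},
        f_statistic=float(fit.fvalue),
        f_df=(int(fit.df_model), int(fit.df_resid)),
        f_pvalue=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )
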