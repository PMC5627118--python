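"""Univariate-response partial least-squares regression (PLS1).

With ~76 candidate covariates and 22 annual observations, ordinary
regression on the full threat table is hopeless: the covariates are
strongly collinear and the design is wildly under-determined.  PLS
extracts latent components of the predictor space that maximize
covariance with the response ("y-aware" dimension reduction), yielding
a small set of components whose correlation loadings identify the
covariates most associated with population size.  This module
implements the NIPALS recursion for a single response, fitted R²,
complete leave-one-out cross-validation (PRESS and Q² = 1 - PRESS/TSS),
the per-component explained-variance decomposition, and the two-stage
variable selection used downstream: a correlation-loading threshold per
component followed by pruning of mutually correlated survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "fit_pls1",
    "loo_cross_validate",
    "select_n_components",
    "explained_variance_report",
    "select_by_loadings",
    "correlation_filter",
]


@dataclass
class PLSModel:
    """Fitted PLS1 model on standardized X and y.

    Component matrices are stored column-per-component; correlation
    loadings are the Pearson correlations between each *undeflated*
    standardized predictor and each score vector, which is the loading
    scale used for variable selection.
    """

    variables: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    weights: np.ndarray       # W  (p x a)
    scores: np.ndarray        # T  (n x a)
    x_loadings: np.ndarray    # P  (p x a)
    y_loadings: np.ndarray    # q  (a,)
    correlation_loadings: np.ndarray  # (p x a)
    explained_y_variance: np.ndarray  # percent per component
    coefficients: np.ndarray  # original-scale slopes (p,)
    intercept: float
    fitted_r2: float
    press: float | None = None
    q2: float | None = None
    dropped_in_folds: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    def loadings_frame(self) -> pd.DataFrame:
        """Long-format table of weights, x-loadings and correlation loadings."""
        rows = []
        for c in range(self.n_components):
            for j, name in enumerate(self.variables):
                rows.append(
                    {
                        "variable": name,
                        "component": c + 1,
                        "weight": self.weights[j, c],
                        "x_loading": self.x_loadings[j, c],
                        "correlation_loading": self.correlation_loadings[j, c],
                    }
                )
        return pd.DataFrame(rows)


def _standardize_xy(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, float]:
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    if np.any(x_sd == 0):
        raise ValueError("zero-variance predictor column")
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd == 0:
        raise ValueError("zero-variance response")
    return (X - x_mean) / x_sd, (y - y_mean) / y_sd, x_mean, x_sd, y_mean, y_sd


def fit_pls1(
    X,
    y,
    n_components: int = 2,
    variables: Sequence[str] | None = None,
) -> PLSModel:
    """Fit a PLS1 model by NIPALS.

    Each component takes weight ``w ∝ X'y`` (unit norm), score
    ``t = Xw``, x-loading ``p = X't/t't`` and y-loading ``q = y't/t't``,
    then deflates both X and y before the next component.  Percent of
    response variance explained by component c is
    ``100 q_c² t_c't_c / TSS``.  X and y are standardized internally
    (mean zero, unit sd, n-1 denominator); reported ``coefficients``
    and ``intercept`` are back-transformed to the original scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if variables is None:
        variables = [f"x{j}" for j in range(p)]
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > min(rank, p):
        raise ValueError(f"n_components={n_components} exceeds effective rank")

    Z, v, x_mean, x_sd, y_mean, y_sd = _standardize_xy(X, y)
    Z0, v0 = Z.copy(), v.copy()
    tss = float(v0 @ v0)

    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    for c in range(n_components):
        w = Z.T @ v
        norm = np.linalg.norm(w)
        if norm == 0:  # response fully deflated; remaining components are null
            W[:, c:] = 0.0
            T[:, c:] = 0.0
            P[:, c:] = 0.0
            q[c:] = 0.0
            break
        w /= norm
        t = Z @ w
        tt = float(t @ t)
        W[:, c] = w
        T[:, c] = t
        P[:, c] = Z.T @ t / tt
        q[c] = float(v @ t) / tt
        Z = Z - np.outer(t, P[:, c])
        v = v - q[c] * t

    explained = 100.0 * q**2 * np.einsum("ij,ij->j", T, T) / tss

    with np.errstate(invalid="ignore"):
        corr = np.array(
            [
                [_corr(Z0[:, j], T[:, c]) for c in range(n_components)]
                for j in range(p)
            ]
        )

    # Standardized-scale regression vector: B = W (P'W)^-1 q.
    b_std = W @ np.linalg.solve(P.T @ W, q)
    coefficients = b_std * y_sd / x_sd
    intercept = y_mean - float(x_mean @ coefficients)

    fitted = Z0 @ b_std
    fitted_r2 = 1.0 - float((v0 - fitted) @ (v0 - fitted)) / tss

    return PLSModel(
        variables=list(variables),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        weights=W,
        scores=T,
        x_loadings=P,
        y_loadings=q,
        correlation_loadings=corr,
        explained_y_variance=explained,
        coefficients=coefficients,
        intercept=intercept,
        fitted_r2=fitted_r2,
    )


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def loo_cross_validate(X, y, n_components: int = 2) -> tuple[float, float]:
    """Complete leave-one-out cross-validation of a PLS1 fit.

    Each observation is predicted by a model refit on the remaining
    n - 1 rows, with centering and scaling re-estimated inside the fold
    so no information leaks from the held-out year.  Returns
    ``(press, q2)`` with PRESS the sum of squared held-out errors and
    Q² = 1 - PRESS/TSS, TSS taken about the full-sample mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < n_components + 2:
        raise ValueError("need n >= n_components + 2 for leave-one-out")
    press = 0.0
    dropped: set[int] = set()
    for i in range(n):
        keep = np.arange(n) != i
        Xf, yf = X[keep], y[keep]
        sd = Xf.std(axis=0, ddof=1)
        cols = np.nonzero(sd > 0)[0]
        dropped.update(np.nonzero(sd == 0)[0])
        model = fit_pls1(Xf[:, cols], yf, n_components=min(n_components, len(cols)))
        pred = model.predict(X[i, cols])
        press += float((y[i] - pred) ** 2)
    if dropped:
        warnings.warn(
            f"zero-variance columns dropped inside folds: {sorted(dropped)}",
            RuntimeWarning,
            stacklevel=2,
        )
    tss = float(((y - y.mean()) ** 2).sum())
    return press, 1.0 - press / tss


def select_n_components(X, y, max_components: int = 5) -> tuple[int, dict[int, float]]:
    """Choose the component count maximizing leave-one-out Q².

    Returns the selected count and the Q² value for every candidate;
    ties go to the smaller count.  The default elsewhere is two fixed
    components (the trend/climate two-regime structure); this selector
    is the data-driven alternative.
    """
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    q2_by_a: dict[int, float] = {}
    for a in range(1, min(max_components, rank, X.shape[1]) + 1):
        _, q2_by_a[a] = loo_cross_validate(X, y, n_components=a)
    best = max(q2_by_a, key=lambda a: (q2_by_a[a], -a))
    return best, q2_by_a


def explained_variance_report(model: PLSModel) -> pd.DataFrame:
    """Per-component percent of response variance, with cumulative R²."""
    pct = model.explained_y_variance
    return pd.DataFrame(
        {
            "component": np.arange(1, model.n_components + 1),
            "explained_y_pct": pct,
            "cumulative_r2": np.cumsum(pct) / 100.0,
        }
    )


def select_by_loadings(
    model: PLSModel, threshold: float = 0.15, top_k: int = 10
) -> pd.DataFrame:
    """Rank variables by absolute correlation loading per component.

    Variables passing ``|loading| >= threshold`` on a component are
    sorted by descending ``|loading|`` and truncated at ``top_k`` per
    component; the union across components is returned with provenance
    (component, rank and loading of each selection).
    """
    rows = []
    for c in range(model.n_components):
        loadings = model.correlation_loadings[:, c]
        order = np.argsort(-np.abs(loadings), kind="stable")
        rank = 0
        for j in order:
            if abs(loadings[j]) < threshold or rank >= top_k:
                break
            rank += 1
            rows.append(
                {
                    "variable": model.variables[j],
                    "component": c + 1,
                    "rank": rank,
                    "correlation_loading": float(loadings[j]),
                }
            )
    return pd.DataFrame(rows, columns=["variable", "component", "rank", "correlation_loading"])


def correlation_filter(
    candidates: Sequence[str],
    data: pd.DataFrame,
    loadings: Mapping[str, float] | None = None,
    variable_meta: pd.DataFrame | None = None,
    r_threshold: float = 0.6,
    region_priority: Sequence[str] = ("north_central", "northeast", "south", "overwinter"),
) -> list[str]:
    """Prune mutually correlated candidates to one representative each.

    Candidates whose pairwise ``|r|`` exceeds ``r_threshold`` are
    clustered (transitively); each cluster keeps one variable, chosen
    by breeding-region priority (the north-central region hosts the
    bulk of summer breeding, so its covariate is preferred), then by
    larger absolute loading, then lexicographically — a deterministic
    rule.  Returns the pruned list in the candidates' original order.
    """
    candidates = list(candidates)
    unknown = set(candidates) - set(data.columns)
    if unknown:
        raise KeyError(f"candidates absent from data: {sorted(unknown)}")
    sub = data[candidates]
    if (sub.std(ddof=1) == 0).any():
        bad = sub.columns[sub.std(ddof=1) == 0].tolist()
        raise ValueError(f"zero-variance candidates: {bad}")
    corr = sub.corr().abs().to_numpy()

    # Union-find over the |r| > threshold graph.
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if corr[i, j] > r_threshold:
                parent[find(i)] = find(j)

    region_rank = {r: k for k, r in enumerate(region_priority)}

    def sort_key(name: str) -> tuple:
        region = (
            variable_meta.loc[name, "region"]
            if variable_meta is not None and name in variable_meta.index
            else None
        )
        loading = abs(loadings.get(name, 0.0)) if loadings is not None else 0.0
        return (region_rank.get(region, len(region_rank)), -loading, name)

    clusters: dict[int, list[str]] = {}
    for i, name in enumerate(candidates):
        clusters.setdefault(find(i), []).append(name)
    keep = {min(members, key=sort_key) for members in clusters.values()}
    return [name for name in candidates if name in keep]
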