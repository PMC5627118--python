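"""Best-subset Gompertz time-series regression with BIC multimodel inference.

The annual log overwinter area ``N_t`` is modelled as a Gompertz
log-abundance regression

    ``N_t = alpha_0 + beta' X_t + eps_t,  eps_t ~ Normal(0, sigma^2)``

where the design may include the previous year's log abundance (making
density dependence an ordinary candidate covariate) alongside habitat,
survival and climate covariates.  All subsets of the reduced variable
list up to a small size are fitted exhaustively, ranked by the Bayesian
information criterion, and summarized by BIC weights, per-variable
importance (the summed weight of models containing the variable),
shrinkage model averaging (absent terms count as zero), and a
confidence set of models within a fixed BIC distance of the best.
Residual autocorrelation diagnostics and an exact-ML AR(1)-error
alternative guard against unmodelled temporal structure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "CandidateFit",
    "ModelSet",
    "enumerate_models",
    "fit_gompertz",
    "bic",
    "model_weights",
    "rank_models",
    "variable_importance",
    "model_average",
    "confidence_set",
    "residual_acf",
    "fit_ar1_gls",
]


@dataclass
class CandidateFit:
    """One covariate subset fitted by Gaussian maximum likelihood."""

    subset: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    sigma2_hat: float
    loglik: float
    r2: float
    bic: float
    delta_bic: float = math.nan
    weight: float = math.nan
    singular: bool = False
    residuals: np.ndarray | None = None
    #: populated only for AR(1)-error fits
    phi: float | None = None
    converged: bool = True


@dataclass
class ModelSet:
    """All enumerated fits plus the derived multimodel quantities."""

    fits: list[CandidateFit]
    variables: list[str]
    n_years: int

    @property
    def ranked(self) -> list[CandidateFit]:
        return sorted(
            (f for f in self.fits if not f.singular),
            key=lambda f: (f.bic, len(f.subset), f.subset),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide model table: one row per candidate, blank absent terms."""
        rows = []
        for f in self.ranked:
            row = {v: f.coefficients.get(v, np.nan) for v in self.variables}
            row.update(
                subset="+".join(f.subset),
                r2=f.r2,
                loglik=f.loglik,
                bic=f.bic,
                delta_bic=f.delta_bic,
                weight=f.weight,
            )
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_models(
    variables: Sequence[str],
    min_size: int = 1,
    max_size: int = 4,
    exact: bool = False,
) -> list[tuple[str, ...]]:
    """All covariate subsets of the requested sizes, lexicographic order.

    With ``exact=True`` only subsets of ``max_size`` are produced; 11
    variables taken exactly 4 at a time yields C(11, 4) = 330 models.
    """
    variables = list(variables)
    if not variables:
        raise ValueError("variable list is empty")
    if max_size > len(variables):
        raise ValueError("max_size exceeds number of variables")
    sizes = [max_size] if exact else range(min_size, max_size + 1)
    return [
        combo for size in sizes for combo in itertools.combinations(variables, size)
    ]


def fit_gompertz(
    data: pd.DataFrame,
    response: pd.Series | str,
    subset: Sequence[str],
    standardize: bool = True,
) -> CandidateFit:
    """Least-squares fit of log abundance on one covariate subset.

    Covariates are standardized (unless pre-standardized upstream), the
    response stays on the log-ha scale.  The Gaussian ML residual
    variance is RSS/n, giving ``loglik = -(n/2)(log(2 pi sigma2) + 1)``.
    Collinear subsets are flagged singular and excluded from ranking.
    """
    if isinstance(response, str):
        y = data[response].to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
    subset = tuple(subset)
    X = data[list(subset)].to_numpy(dtype=float)
    n = len(y)
    if n <= len(subset) + 2:
        raise ValueError("need n > n_covariates + 2 observations")
    if standardize and subset:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            return _singular_fit(subset)
        X = (X - X.mean(axis=0)) / sd
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return _singular_fit(subset)
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    sigma2 = rss / n
    loglik = gaussian_loglik(rss, n)
    k = len(subset) + 2  # intercept + slopes + residual variance
    return CandidateFit(
        subset=subset,
        coefficients=dict(zip(subset, coef[1:])),
        intercept=float(coef[0]),
        sigma2_hat=sigma2,
        loglik=loglik,
        r2=1.0 - rss / tss,
        bic=bic(loglik, len(subset), n),
        residuals=resid,
    )


def _singular_fit(subset: tuple[str, ...]) -> CandidateFit:
    return CandidateFit(
        subset=subset,
        coefficients={},
        intercept=math.nan,
        sigma2_hat=math.nan,
        loglik=-math.inf,
        r2=math.nan,
        bic=math.inf,
        singular=True,
    )


def gaussian_loglik(rss: float, n: int) -> float:
    """Profile Gaussian log-likelihood at the ML variance RSS/n."""
    if rss <= 0:
        return math.inf
    return -(n / 2.0) * (math.log(2.0 * math.pi * rss / n) + 1.0)


def bic(loglik: float, n_covariates: int, n_years: int) -> float:
    """Bayesian information criterion, ``-2 logLik + k ln(n)``.

    The parameter count ``k = n_covariates + 2`` charges for the
    intercept and the residual variance as well as the slopes.
    """
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    if not math.isfinite(loglik):
        raise ValueError("loglik must be finite")
    k = n_covariates + 2
    return -2.0 * loglik + k * math.log(n_years)


def model_weights(bics: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """BIC differences and normalized weights over a model set.

    ``delta_i = BIC_i - min BIC``; ``w_i = exp(-delta_i/2)`` normalized
    to sum to one.  Non-finite BICs (singular fits) receive zero weight.
    """
    bics = np.asarray(bics, dtype=float)
    finite = np.isfinite(bics)
    if not finite.any():
        raise ValueError("no finite BIC values")
    delta = bics - bics[finite].min()
    raw = np.where(finite, np.exp(-0.5 * delta), 0.0)
    return delta, raw / raw.sum()


def rank_models(
    data: pd.DataFrame,
    response: pd.Series | str,
    variables: Sequence[str],
    min_size: int = 1,
    max_size: int = 4,
    exact: bool = False,
    standardize: bool = True,
) -> ModelSet:
    """Fit every enumerated subset and attach deltas and weights."""
    subsets = enumerate_models(variables, min_size, max_size, exact)
    fits = [fit_gompertz(data, response, s, standardize=standardize) for s in subsets]
    usable = [f for f in fits if not f.singular]
    delta, w = model_weights([f.bic for f in usable])
    for f, d, wi in zip(usable, delta, w):
        f.delta_bic = float(d)
        f.weight = float(wi)
    n = len(data)
    return ModelSet(fits=fits, variables=list(variables), n_years=n)


def variable_importance(model_set: ModelSet) -> pd.Series:
    """Per-variable sum of the weights of models containing it."""
    importance = dict.fromkeys(model_set.variables, 0.0)
    for f in model_set.fits:
        if f.singular:
            continue
        for v in f.subset:
            importance[v] += f.weight
    return pd.Series(importance).sort_values(ascending=False)


def model_average(
    model_set: ModelSet, within_delta: float | None = None
) -> pd.Series:
    """Shrinkage-averaged coefficients over the enumerated set.

    ``beta_bar_j = sum_i w_i beta_hat_ij`` with a zero contribution from
    models excluding j, so weakly supported effects are pulled toward
    zero in proportion to their importance.  ``within_delta`` restricts
    the averaging set to models within that many BIC units of the best,
    with weights renormalized over that set.
    """
    if within_delta is None:
        fits = [f for f in model_set.fits if not f.singular]
    else:
        fits = confidence_set(model_set, within_delta)
    total = sum(f.weight for f in fits)
    avg = dict.fromkeys(model_set.variables, 0.0)
    for f in fits:
        for v, b in f.coefficients.items():
            avg[v] += f.weight / total * b
    return pd.Series(avg)


def confidence_set(model_set: ModelSet, delta_max: float = 10.0) -> list[CandidateFit]:
    """Best-supported models within ``delta_max`` BIC units of the best."""
    return [f for f in model_set.ranked if f.delta_bic <= delta_max]


def residual_acf(fit: CandidateFit, n_lags: int = 10) -> pd.DataFrame:
    """Sample autocorrelation of a fit's residuals with 95% bounds.

    Bounds are the white-noise approximation ``+-1.96/sqrt(n)``; a lag
    (>= 1) outside the bounds is flagged as residual temporal structure.
    """
    from statsmodels.tsa.stattools import acf

    resid = np.asarray(fit.residuals, dtype=float)
    if len(resid) <= n_lags:
        raise ValueError("residual series shorter than requested lags")
    if resid.std() == 0:
        raise ValueError("constant residuals")
    values = acf(resid, nlags=n_lags, fft=False)
    bound = 1.96 / math.sqrt(len(resid))
    lags = np.arange(n_lags + 1)
    return pd.DataFrame(
        {
            "lag": lags,
            "acf": values,
            "lower": -bound,
            "upper": bound,
            "flagged": (lags >= 1) & (np.abs(values) > bound),
        }
    )


def fit_ar1_gls(
    data: pd.DataFrame,
    response: pd.Series | str,
    subset: Sequence[str],
    standardize: bool = True,
) -> tuple[CandidateFit, float]:
    """Exact Gaussian ML regression with AR(1) errors.

    The error process ``eps_t = phi eps_{t-1} + u_t`` is profiled out on
    a coarse grid over ``phi in (-1, 1)`` followed by local refinement;
    each candidate ``phi`` is evaluated by the exact (stationary)
    likelihood via the Prais-Winsten transform, including the
    ``log(1 - phi^2)/2`` Jacobian term for the first observation.  The
    BIC charges one extra parameter relative to the white-noise fit.
    Returns the AR(1) fit and its BIC difference versus ordinary least
    squares (positive when OLS is preferred).
    """
    if isinstance(response, str):
        y = data[response].to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
    subset = tuple(subset)
    X = data[list(subset)].to_numpy(dtype=float)
    n = len(y)
    if standardize and subset:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance covariate in subset")
        X = (X - X.mean(axis=0)) / sd
    design = np.column_stack([np.ones(n), X])

    def profile_negloglik(phi: float) -> float:
        return -_ar1_loglik(design, y, phi)[0]

    grid = np.linspace(-0.95, 0.95, 39)
    best_phi = float(grid[np.argmin([profile_negloglik(p) for p in grid])])
    lo, hi = max(best_phi - 0.06, -0.999), min(best_phi + 0.06, 0.999)
    result = minimize_scalar(profile_negloglik, bounds=(lo, hi), method="bounded")
    converged = bool(result.success)
    phi_hat = float(result.x) if converged else best_phi
    loglik, coef, resid, sigma2_u = _ar1_loglik(design, y, phi_hat)

    k = len(subset) + 3  # intercept + slopes + variance + phi
    ar1_bic = -2.0 * loglik + k * math.log(n)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(resid @ resid)
    ols = fit_gompertz(data, response, subset, standardize=standardize)
    fit = CandidateFit(
        subset=subset,
        coefficients=dict(zip(subset, coef[1:])),
        intercept=float(coef[0]),
        sigma2_hat=sigma2_u,
        loglik=loglik,
        r2=1.0 - rss / tss,
        bic=ar1_bic,
        phi=phi_hat,
        converged=converged,
        residuals=resid,
    )
    return fit, ar1_bic - ols.bic


def _ar1_loglik(
    design: np.ndarray, y: np.ndarray, phi: float
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Exact stationary AR(1)-error likelihood profiled over beta, sigma."""
    n = len(y)
    scale = math.sqrt(1.0 - phi**2)
    ys = np.concatenate([[scale * y[0]], y[1:] - phi * y[:-1]])
    Xs = np.vstack([scale * design[:1], design[1:] - phi * design[:-1]])
    coef, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    innov = ys - Xs @ coef
    rss = float(innov @ innov)
    sigma2_u = rss / n
    loglik = -(n / 2.0) * (math.log(2.0 * math.pi * sigma2_u) + 1.0) + 0.5 * math.log(
        1.0 - phi**2
    )
    resid = y - design @ coef
    return loglik, coef, resid, sigma2_u
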