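"""Recursive three-variable structural path model.

The best-subset regressions identify cumulative glyphosate application
as the covariate most consistently associated with overwinter
population size; the hypothesized mechanism is loss of milkweed, the
monarch's obligate larval host plant.  This module fits the log-log
causal chain

    ``log(milkweed)   = gamma * log(cumulative glyphosate)``
    ``log(population) = delta * log(milkweed)``

as a covariance-structure model on standardized variables.  The system
is recursive with no direct glyphosate -> population path, so maximum
likelihood reduces to per-equation least squares; the one omitted path
leaves a single testable degree of freedom, assessed by the ML
chi-square discrepancy together with RMSEA and CFI fit indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PathFit", "fit_path_model", "fit_indices", "independence_baseline"]


@dataclass
class PathFit:
    """Standardized path estimates and covariance-structure fit."""

    gamma: float
    delta: float
    r2_milkweed: float
    r2_population: float
    chi2: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    n: int
    chi2_baseline: float
    df_baseline: int


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance input series")
    return (v - v.mean()) / sd


def fit_path_model(
    x,
    m,
    y,
    chi2_scale: str = "nminus1",
) -> PathFit:
    """Fit the glyphosate -> milkweed -> population path model.

    Parameters
    ----------
    x, m, y
        Log cumulative glyphosate, log milkweed resource and log
        overwinter population series of equal length (n >= 5).
    chi2_scale
        ``"nminus1"`` (Wishart convention, default) or ``"n"``:
        multiplier applied to the ML discrepancy to form the chi-square
        statistic.

    The free parameters are the two path coefficients and the three
    (residual) variances; with 3 observed variables there are 6 sample
    moments, leaving df = 1 for the omitted direct x -> y path.  The
    discrepancy is ``F_ML = log|Sigma| + tr(S Sigma^-1) - log|S| - 3``
    evaluated at the ML estimates.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (len(x) == len(m) == len(y)):
        raise ValueError("series must have equal length")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if not (np.isfinite(x).all() and np.isfinite(m).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if chi2_scale not in ("nminus1", "n"):
        raise ValueError("chi2_scale must be 'nminus1' or 'n'")

    data = np.column_stack([_standardize(x), _standardize(m), _standardize(y)])
    S = np.cov(data, rowvar=False, ddof=1)

    # ML for the recursive system = per-equation least squares.
    gamma = S[0, 1] / S[0, 0]
    delta = S[1, 2] / S[1, 1]
    psi_m = S[1, 1] - gamma**2 * S[0, 0]
    psi_y = S[2, 2] - delta**2 * S[1, 1]
    r2_m = gamma**2 * S[0, 0] / S[1, 1]
    r2_y = delta**2 * S[1, 1] / S[2, 2]

    sigma_mm = gamma**2 * S[0, 0] + psi_m
    implied = np.array(
        [
            [S[0, 0], gamma * S[0, 0], delta * gamma * S[0, 0]],
            [gamma * S[0, 0], sigma_mm, delta * sigma_mm],
            [delta * gamma * S[0, 0], delta * sigma_mm, delta**2 * sigma_mm + psi_y],
        ]
    )
    sign_i, logdet_i = np.linalg.slogdet(implied)
    sign_s, logdet_s = np.linalg.slogdet(S)
    multiplier = n - 1 if chi2_scale == "nminus1" else n
    if sign_i <= 0 or sign_s <= 0:
        # Exactly deterministic chains collapse S to a singular matrix;
        # when the implied covariance reproduces it the fit is perfect.
        if np.allclose(implied, S, atol=1e-8):
            chi2 = 0.0
        else:
            raise ValueError("singular sample covariance")
    else:
        f_ml = logdet_i + float(np.trace(S @ np.linalg.inv(implied))) - logdet_s - 3.0
        chi2 = max(multiplier * f_ml, 0.0)
    df = 1

    try:
        chi2_b, df_b = independence_baseline(S, n, chi2_scale)
    except ValueError:
        chi2_b, df_b = math.inf, 3  # singular R: baseline misfit unbounded
    rmsea, cfi, p_value = fit_indices(chi2, df, n, chi2_b, df_b)
    return PathFit(
        gamma=float(gamma),
        delta=float(delta),
        r2_milkweed=float(r2_m),
        r2_population=float(r2_y),
        chi2=float(chi2),
        df=df,
        p_value=float(p_value),
        rmsea=float(rmsea),
        cfi=float(cfi),
        n=n,
        chi2_baseline=float(chi2_b),
        df_baseline=df_b,
    )


def independence_baseline(
    S: np.ndarray, n: int, chi2_scale: str = "nminus1"
) -> tuple[float, int]:
    """Chi-square of the independence model (all covariances zero).

    With free variances the ML discrepancy reduces to ``-log|R|`` for
    the sample correlation matrix R; df equals the number of off-diagonal
    moments (3 for three observed variables).
    """
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("singular correlation matrix")
    f_b = -logdet
    multiplier = n - 1 if chi2_scale == "nminus1" else n
    p = S.shape[0]
    return max(multiplier * f_b, 0.0), p * (p - 1) // 2


def fit_indices(
    chi2: float,
    df: int,
    n: int,
    chi2_baseline: float,
    df_baseline: int = 3,
) -> tuple[float, float, float]:
    """RMSEA, CFI and the chi-square p-value.

    ``rmsea = sqrt(max(chi2 - df, 0) / (df (n - 1)))`` penalizes misfit
    per degree of freedom and sample size; ``cfi`` compares the model's
    noncentrality ``max(chi2 - df, 0)`` to the independence baseline's,
    so any model with ``chi2 <= df`` scores RMSEA 0 and CFI 1.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    excess = max(chi2 - df, 0.0)
    rmsea = math.sqrt(excess / (df * (n - 1)))
    denom = max(chi2_baseline - df_baseline, excess, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    p_value = float(stats.chi2.sf(chi2, df))
    return rmsea, cfi, p_value


def simulate_path_data(
    n: int,
    gamma: float = -0.18,
    delta: float = 1.78,
    sd_m: float = 1.0,
    sd_y: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one dataset from the recursive path model (no direct x -> y).

    ``x`` is standard normal; ``m = gamma x + e_m`` and
    ``y = delta m + e_y`` with independent Gaussian residuals.  Used for
    null-distribution calibration of the chi-square statistic and for
    coefficient-recovery studies at the study's sample size.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    m = gamma * x + rng.normal(scale=sd_m, size=n)
    y = delta * m + rng.normal(scale=sd_y, size=n)
    return x, m, y
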