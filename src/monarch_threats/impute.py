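"""DINEOF-style gap filling of the covariate matrix.

Missing covariate cells are interpolated with data-interpolating
empirical orthogonal functions: the year-by-variable matrix is
repeatedly decomposed by truncated singular value decomposition, missing
cells are overwritten with the rank-k reconstruction, and the number of
retained modes k is chosen by cross-validation against a set of
observed cells withheld as reference values.  The covariates mix units
(kg of herbicide, ha of forest, degC, proportions), so columns are
standardized before each decomposition; the standardization constants
are re-estimated from the current completed matrix every iteration, so
at convergence the column statistics are those of the completed data
rather than of the gappy observations.  Modes are added incrementally,
each mode count warm-started from the previous one's solution, as in
the classical DINEOF recursion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ImputationResult", "dineof_impute", "mask_reference_cells"]


@dataclass
class ImputationResult:
    """Completed matrix plus the cross-validation record behind it.

    ``cv_rmse_by_modes`` maps each candidate mode count to the RMSE on
    the withheld reference cells, measured on the standardized scale so
    columns with different units contribute comparably; ``n_iterations``
    uses key 0 for the final refit.
    """

    completed: np.ndarray
    n_modes: int
    cv_rmse_by_modes: dict[int, float]
    n_iterations: dict[int, int]
    converged: dict[int, bool]

    @property
    def convergence_warning(self) -> bool:
        return not all(self.converged.values())


def mask_reference_cells(
    mask: np.ndarray, cv_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Withhold a random fraction of the *observed* cells for validation.

    Returns row and column index arrays of the withheld cells, drawn
    without replacement from cells not already missing; deterministic
    per seed.  At least one cell is always withheld.
    """
    if not 0 < cv_fraction < 0.5:
        raise ValueError("cv_fraction must lie in (0, 0.5)")
    mask = np.asarray(mask, dtype=bool)
    obs_rows, obs_cols = np.nonzero(~mask)
    if len(obs_rows) == 0:
        raise ValueError("matrix has no observed cells")
    n_ref = max(1, int(round(cv_fraction * len(obs_rows))))
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(obs_rows), size=n_ref, replace=False)
    return obs_rows[pick], obs_cols[pick]


def _column_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return mean, np.where(sd > 0, sd, 1.0)


def _iterate_modes(
    x: np.ndarray,
    fill_mask: np.ndarray,
    k: int,
    tol: float,
    max_iter: int,
    start: np.ndarray | None = None,
    init_fill: np.ndarray | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Alternate standardize / rank-k truncate / overwrite fillable cells.

    ``start`` warm-starts from a previous mode count's solution;
    otherwise fillable cells begin at ``init_fill`` (the observed-cell
    column means).  Convergence is declared when the RMS change of the
    fillable cells, on the standardized scale, moves by less than
    ``tol`` relatively (or falls below ``tol`` outright).
    """
    if start is not None:
        filled = start.copy()
    else:
        filled = x.copy()
        filled[fill_mask] = init_fill[fill_mask]
    prev_rmse: float | None = None
    for iteration in range(1, max_iter + 1):
        mean, sd = _column_stats(filled)
        z = (filled - mean) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        recon = ((u[:, :k] * s[:k]) @ vt[:k]) * sd + mean
        rmse = float(
            np.sqrt(np.mean(((recon[fill_mask] - filled[fill_mask]) / sd_of(fill_mask, sd)) ** 2))
        )
        filled[fill_mask] = recon[fill_mask]
        if rmse <= tol or (
            prev_rmse is not None
            and abs(prev_rmse - rmse) <= tol * max(prev_rmse, 1e-12)
        ):
            return filled, iteration, True
        prev_rmse = rmse
    return filled, max_iter, False


def sd_of(fill_mask: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Per-cell column sd for the fillable cells, for scale-free RMS."""
    _, cols = np.nonzero(fill_mask)
    return sd[cols]


def dineof_impute(
    data: np.ndarray,
    max_modes: int | None = None,
    cv_fraction: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> ImputationResult:
    """Fill missing cells by iterative truncated-SVD reconstruction.

    Parameters
    ----------
    data
        Year-by-variable matrix with missing cells as NaN; every column
        needs at least two observed values.
    max_modes
        Largest EOF count tried; defaults to ``min(rows, cols) - 1``
        (one less than full rank, so truncation always smooths).
    cv_fraction
        Fraction of observed cells withheld as reference values for
        choosing the number of modes.
    tol
        Relative change in reconstruction RMSE declaring convergence.
    max_iter
        Iteration cap per candidate mode count; non-convergence is
        reported via a warning and the best iterate is kept.
    seed
        Seed for the reference-cell draw.

    The selected mode count minimizes the withheld-cell RMSE (ties go to
    the smaller k); the returned matrix is refit at that count with all
    observed cells participating, so observed values pass through
    unchanged.
    """
    x = np.asarray(data, dtype=float).copy()
    if x.ndim != 2:
        raise ValueError("data must be a 2-D matrix")
    miss = np.isnan(x)
    n_rows, n_cols = x.shape
    if ((~miss).sum(axis=0) < 2).any():
        raise ValueError("every column needs at least 2 observed values")
    if max_modes is None:
        max_modes = max(1, min(n_rows, n_cols) - 1)
    if max_modes > min(n_rows, n_cols):
        raise ValueError("max_modes cannot exceed min(rows, cols)")

    if not miss.any():
        return ImputationResult(
            completed=x, n_modes=1, cv_rmse_by_modes={}, n_iterations={}, converged={}
        )

    # Initial guesses: observed-cell column means (broadcast per column).
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        obs_mean = np.nanmean(x, axis=0)
        obs_sd = np.nanstd(x, axis=0, ddof=1)
    obs_sd = np.where(obs_sd > 0, obs_sd, 1.0)
    init_fill = np.broadcast_to(obs_mean, x.shape)

    ref_rows, ref_cols = mask_reference_cells(miss, cv_fraction, seed)
    ref_values = x[ref_rows, ref_cols].copy()
    cv_fill = miss.copy()
    cv_fill[ref_rows, ref_cols] = True
    x_cv = x.copy()
    x_cv[ref_rows, ref_cols] = np.nan

    cv_rmse: dict[int, float] = {}
    n_iterations: dict[int, int] = {}
    converged: dict[int, bool] = {}
    filled: np.ndarray | None = None
    for k in range(1, max_modes + 1):
        filled, iters, ok = _iterate_modes(
            x_cv, cv_fill, k, tol, max_iter, start=filled, init_fill=init_fill
        )
        cv_rmse[k] = float(
            np.sqrt(
                np.mean(
                    ((filled[ref_rows, ref_cols] - ref_values) / obs_sd[ref_cols]) ** 2
                )
            )
        )
        n_iterations[k] = iters
        converged[k] = ok
        if not ok:
            warnings.warn(
                f"DINEOF did not converge within {max_iter} iterations at k={k}",
                RuntimeWarning,
                stacklevel=2,
            )
    best_k = min(cv_rmse, key=lambda k: (cv_rmse[k], k))

    final: np.ndarray | None = None
    for k in range(1, best_k + 1):
        final, iters, ok = _iterate_modes(
            x, miss, k, tol, max_iter, start=final, init_fill=init_fill
        )
    n_iterations[0] = iters
    if not ok:
        warnings.warn(
            f"final DINEOF refit did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    completed = final
    completed[~miss] = x[~miss]  # observed cells restored bit-exactly
    return ImputationResult(
        completed=completed,
        n_modes=best_k,
        cv_rmse_by_modes=cv_rmse,
        n_iterations=n_iterations,
        converged=converged,
    )
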