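"""Bootstrap deviance selection of the number of constituent cell types.

For each candidate K, specimens are resampled with replacement, the
factorization is refit on the bootstrap sample (warm-started from the
full-data fit), and the fit is scored on the specimens left out of the
bootstrap: each held-out specimen's proportions are re-solved against the
bootstrap methylomes (the methylomes themselves are not refit) and a
Gaussian deviance

    sum_j sum_{i not in b} [ log(2 pi sigma_j^2) + r_ij^2 / sigma_j^2 ]

is accumulated, with per-CpG residual variances sigma_j^2 estimated from
the bootstrap fit (residual sum of squares over residual degrees of
freedom, floored at 1e-9 so the deviance stays finite).  K = 1 is scored
against the bootstrap row-mean model.  The same bootstrap resamples are
used across the whole K grid, which removes between-K resampling noise
from the profile; K_hat minimizes the mean bootstrap deviance (ties break
toward smaller K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _qp
from .deconvolution import DeconvolutionFit, deconvolve, fit_k_sequence
from .io import BetaMatrix

VARIANCE_FLOOR = 1e-9

__all__ = ["FitParams", "DevianceProfile", "bootstrap_deviance", "select_K"]


@dataclass
class FitParams:
    """Deconvolution settings used inside the bootstrap.

    ``boot_iter`` caps the alternating iterations of the warm-started
    bootstrap refits; the full-data fits use ``n_iter``.
    """

    n_iter: int = 25
    n_restarts: int = 5
    boot_iter: int = 10
    tol: float = 1e-6


@dataclass
class DevianceProfile:
    K_values: list[int]
    deviance_draws: dict[int, np.ndarray]
    summary: pd.DataFrame
    K_hat: int
    statistic: str = "mean"
    boot_indices: list[np.ndarray] = field(default_factory=list, repr=False)


def _draw_boot_indices(n: int, n_boot: int, rng: np.random.Generator) -> list[np.ndarray]:
    """n_boot index vectors (with replacement); redraw until the out-of-bag
    set is non-empty."""
    out = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while len(np.unique(idx)) == n:
            idx = rng.integers(0, n, size=n)
        out.append(idx)
    return out


def _boot_beta(beta: BetaMatrix, idx: np.ndarray) -> BetaMatrix:
    ids = [f"{beta.specimen_ids[i]}__b{p}" for p, i in enumerate(idx)]
    return BetaMatrix(beta.values[:, idx].copy(), list(beta.cpg_ids), ids)


def _row_mean_model(Yb: np.ndarray) -> np.ndarray:
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(Yb, axis=1)
    return np.nan_to_num(mu, nan=0.0)


def _oob_residuals(Y: np.ndarray, M: np.ndarray, oob: np.ndarray) -> np.ndarray:
    """Residuals of out-of-bag specimens after re-solving their proportions
    against the bootstrap methylomes."""
    Yo = Y[:, oob]
    W = np.zeros((len(oob), M.shape[1]))
    complete = ~np.isnan(Yo).any(axis=0)
    if complete.any():
        W[complete] = _qp.subsimplex_lsq_multi(M.T @ M, M.T @ Yo[:, complete]).T
    for i in np.flatnonzero(~complete):
        obs = ~np.isnan(Yo[:, i])
        W[i] = _qp.subsimplex_lsq(M[obs], Yo[obs, i])
    return Yo - M @ W.T


def bootstrap_deviance(beta: BetaMatrix, K: int, n_boot: int = 50, seed: int = 0,
                       fit_params: FitParams | None = None,
                       warm_fit: DeconvolutionFit | None = None,
                       boot_indices: list[np.ndarray] | None = None) -> np.ndarray:
    """Out-of-bag Gaussian deviances for one candidate K (one per bootstrap)."""
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    Y = beta.values
    m, n = Y.shape
    if n < 4:
        raise ValueError("need at least 4 specimens")
    fp = fit_params or FitParams()
    rng = np.random.default_rng(seed)
    if boot_indices is None:
        boot_indices = _draw_boot_indices(n, n_boot, rng)

    warm_M = None
    if K >= 2:
        if warm_fit is None:
            warm_fit = deconvolve(beta, K, n_iter=fp.n_iter, n_restarts=fp.n_restarts,
                                  seed=seed, tol=fp.tol)
        warm_M = warm_fit.M.values

    deviances = np.empty(len(boot_indices))
    for b, idx in enumerate(boot_indices):
        if K > len(np.unique(idx)):
            raise ValueError("K exceeds the bootstrap sample's distinct-specimen count")
        oob = np.setdiff1d(np.arange(n), idx)
        Yb = Y[:, idx]
        if K == 1:
            mu = _row_mean_model(Yb)
            resid_in = Yb - mu[:, None]
            dof = np.maximum((~np.isnan(Yb)).sum(axis=1) - 1, 1)
            r_oob = Y[:, oob] - mu[:, None]
        else:
            bb = _boot_beta(beta, idx)
            fit = deconvolve(bb, K, n_iter=fp.boot_iter, n_restarts=0, seed=seed,
                             warm_start=warm_M, tol=fp.tol)
            resid_in = Yb - fit.M.values @ fit.Omega.values.T
            dof = np.maximum((~np.isnan(Yb)).sum(axis=1) - K, 1)
            r_oob = _oob_residuals(Y, fit.M.values, oob)
        rss = np.nansum(resid_in * resid_in, axis=1)
        sigma2 = np.maximum(rss / dof, VARIANCE_FLOOR)
        n_obs_oob = (~np.isnan(r_oob)).sum(axis=1)
        dev = (n_obs_oob * np.log(2.0 * np.pi * sigma2)
               + np.nansum(r_oob * r_oob, axis=1) / sigma2)
        deviances[b] = float(dev.sum())
    return deviances


def select_K(beta: BetaMatrix, K_max: int = 10, n_boot: int = 50, seed: int = 0,
             fit_params: FitParams | None = None, statistic: str = "mean") -> DevianceProfile:
    """Scan K = 1..K_max and pick the bootstrap-deviance minimizer.

    K_max is capped at n - 2 to leave room for out-of-bag assessment.  All
    K share one stream of bootstrap resamples.  ``statistic`` is "mean"
    (default) or "median".
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    n = beta.shape[1]
    K_cap = min(K_max, n - 2)
    if K_cap < 1:
        raise ValueError("too few specimens for bootstrap selection")
    fp = fit_params or FitParams()
    rng = np.random.default_rng(seed)
    boot_indices = _draw_boot_indices(n, n_boot, rng)
    # resamples are shared across the K grid, so the largest fit-able K is
    # bounded by the sparsest resample's distinct-specimen count
    K_cap = min(K_cap, min(len(np.unique(idx)) for idx in boot_indices))
    K_values = list(range(1, K_cap + 1))

    full_fits = fit_k_sequence(beta, [k for k in K_values if k >= 2],
                               n_iter=fp.n_iter, n_restarts=fp.n_restarts,
                               seed=seed, tol=fp.tol)
    draws: dict[int, np.ndarray] = {}
    for K in K_values:
        draws[K] = bootstrap_deviance(beta, K, seed=seed, fit_params=fp,
                                      warm_fit=full_fits.get(K),
                                      boot_indices=boot_indices)
    rows = []
    for K in K_values:
        d = draws[K]
        rows.append({"K": K, "mean": d.mean(), "median": float(np.median(d)),
                     "q25": float(np.quantile(d, 0.25)),
                     "q75": float(np.quantile(d, 0.75))})
    summary = pd.DataFrame(rows)
    crit = summary[statistic].to_numpy()
    K_hat = K_values[int(np.argmin(crit))]  # argmin takes the first (smallest K) on ties
    return DevianceProfile(K_values, draws, summary, K_hat, statistic, boot_indices)
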