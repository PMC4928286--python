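"""Constrained factorization of beta matrices into methylomes and proportions.

The model is Y = M Omega', with Y an m x n beta matrix, M an m x K matrix of
putative cell-type methylomes (entries in [0, 1]) and Omega an n x K matrix
of per-specimen mixture weights on the sub-simplex (non-negative, row sums
at most one).  Fitting alternates two exact convex half-steps:

* proportions: for each specimen, sub-simplex-constrained least squares of
  its observed betas on the current methylomes;
* methylomes: for each CpG, box-constrained least squares of its observed
  betas on the current proportions.

Each half-step minimizes the residual sum of squares over observed entries
in one block, so the recorded rss trace is non-increasing.  Multiple starts
(Ward-clustering means, plus jittered copies) guard against local optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from . import _qp
from .io import BetaMatrix

__all__ = [
    "MethylomeMatrix",
    "ProportionMatrix",
    "DeconvolutionFit",
    "MixingMatrix",
    "initialize_methylomes",
    "solve_proportions",
    "solve_methylome_row",
    "deconvolve",
    "fit_k_sequence",
    "project_to_reference",
    "residualize_against_reference",
]


@dataclass
class MethylomeMatrix:
    """CpG x cell-type matrix of methylation fractions in [0, 1]."""

    values: np.ndarray
    cpg_ids: list[str]
    type_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[1] < 1:
            raise ValueError("K must be >= 1")
        if np.nanmin(self.values) < -1e-9 or np.nanmax(self.values) > 1 + 1e-9:
            raise ValueError("methylome entries must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def K(self) -> int:
        return self.values.shape[1]


@dataclass
class ProportionMatrix:
    """Specimen x cell-type mixture weights on the sub-simplex."""

    values: np.ndarray
    specimen_ids: list[str]
    type_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.min() < -1e-10 or self.values.max() > 1 + 1e-8:
            raise ValueError("proportions must lie in [0, 1]")
        if (self.values.sum(axis=1) > 1 + 1e-8).any():
            raise ValueError("proportion rows must sum to at most 1")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def K(self) -> int:
        return self.values.shape[1]


@dataclass
class DeconvolutionFit:
    M: MethylomeMatrix
    Omega: ProportionMatrix
    rss: float
    n_iter: int
    converged: bool
    restart_index: int
    rss_history: list[float] = field(default_factory=list)


@dataclass
class MixingMatrix:
    """K_ref x K_free weights expressing free methylomes as sub-simplex
    combinations of reference methylomes (one column per free type)."""

    values: np.ndarray
    reference_labels: list[str]
    free_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1e-10:
            raise ValueError("mixing weights must be non-negative")
        if (self.values.sum(axis=0) > 1 + 1e-8).any():
            raise ValueError("mixing columns must sum to at most 1")
        np.clip(self.values, 0.0, None, out=self.values)


def initialize_methylomes(beta: BetaMatrix, K: int, seed: int = 0) -> MethylomeMatrix:
    """Initial M from Ward clustering of specimens.

    Specimens are clustered on complete-data CpGs (Euclidean distance, Ward
    linkage) into K groups; the initial methylomes are the per-group mean
    profiles (observed entries only).  Deterministic given the input.
    """
    Y = beta.values
    m, n = Y.shape
    if K > n:
        raise ValueError(f"K={K} exceeds number of specimens n={n}")
    if K == 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prof = np.nanmean(Y, axis=1)
        prof = np.nan_to_num(prof, nan=0.0)
        return MethylomeMatrix(prof[:, None], list(beta.cpg_ids), ["type_1"])
    complete = ~np.isnan(Y).any(axis=1)
    Yc = Y[complete] if complete.any() else np.nan_to_num(Y, nan=0.0)
    distinct = np.unique(Yc.T, axis=0).shape[0]
    if distinct < K:
        raise ValueError(f"only {distinct} distinct specimen profiles for K={K}")
    Z = linkage(Yc.T, method="ward")
    labels = fcluster(Z, t=K, criterion="maxclust")
    cols = np.empty((m, K))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        overall = np.nan_to_num(np.nanmean(Y, axis=1), nan=0.0)
        for k in range(K):
            grp = labels == (k + 1)
            prof = np.nanmean(Y[:, grp], axis=1)
            cols[:, k] = np.where(np.isnan(prof), overall, prof)
    return MethylomeMatrix(cols, list(beta.cpg_ids), [f"type_{k+1}" for k in range(K)])


def solve_proportions(y: np.ndarray, M: MethylomeMatrix | np.ndarray) -> np.ndarray:
    """One specimen's mixture weights: argmin ||y - M w||^2 over observed
    entries, subject to w >= 0 and sum(w) <= 1 (KKT residual <= 1e-8)."""
    A = M.values if isinstance(M, MethylomeMatrix) else np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    Ao, yo = A[obs], y[obs]
    if np.linalg.matrix_rank(Ao) < A.shape[1]:
        warnings.warn("methylome matrix rank-deficient on observed rows; "
                      "returning a minimum-norm optimum", RuntimeWarning)
    return _qp.subsimplex_lsq(Ao, yo)


def solve_methylome_row(y_row: np.ndarray, Omega: ProportionMatrix | np.ndarray) -> np.ndarray:
    """One CpG's methylome values: argmin ||y_row - Omega mu||^2 over
    observed specimens, subject to 0 <= mu <= 1."""
    A = Omega.values if isinstance(Omega, ProportionMatrix) else np.asarray(Omega, dtype=float)
    y = np.asarray(y_row, dtype=float)
    obs = ~np.isnan(y)
    if obs.sum() < A.shape[1]:
        warnings.warn("fewer observed specimens than cell types for this CpG; "
                      "returning a minimum-norm box-feasible optimum", RuntimeWarning)
    return _qp.box_lsq(A[obs], y[obs])


def _omega_step(Y: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Solve all specimens' proportions against M (batched over complete
    columns; per-specimen on columns with missing entries)."""
    m, n = Y.shape
    K = M.shape[1]
    W = np.zeros((n, K))
    col_complete = ~np.isnan(Y).any(axis=0)
    if col_complete.any():
        Q = M.T @ M
        C = M.T @ Y[:, col_complete]
        W[col_complete] = _qp.subsimplex_lsq_multi(Q, C).T
    for i in np.flatnonzero(~col_complete):
        obs = ~np.isnan(Y[:, i])
        W[i] = _qp.subsimplex_lsq(M[obs], Y[obs, i])
    return W


def _m_step(Y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve all CpG rows' methylomes against Omega=W."""
    m, n = Y.shape
    K = W.shape[1]
    M = np.zeros((m, K))
    row_complete = ~np.isnan(Y).any(axis=1)
    if row_complete.any():
        Q = W.T @ W
        C = W.T @ Y[row_complete].T
        M[row_complete] = _qp.box_lsq_multi(Q, C).T
    for j in np.flatnonzero(~row_complete):
        obs = ~np.isnan(Y[j])
        M[j] = _qp.box_lsq(W[obs], Y[j, obs])
    return M


def _rss(Y: np.ndarray, M: np.ndarray, W: np.ndarray) -> float:
    R = Y - M @ W.T
    return float(np.nansum(R * R))


def deconvolve(beta: BetaMatrix, K: int, n_iter: int = 25, n_restarts: int = 5,
               seed: int = 0, warm_start: MethylomeMatrix | np.ndarray | None = None,
               tol: float = 1e-6, extra_starts: list[np.ndarray] | None = None) -> DeconvolutionFit:
    """Fit Y = M Omega' by alternating constrained least squares.

    From each start (Ward-clustering means, jittered copies, an optional
    warm start and optional extra starts) the fit alternates the proportion
    and methylome half-steps for up to ``n_iter`` outer iterations, stopping
    early when the relative rss change falls below ``tol``.  The start with
    the lowest rss (over observed entries) wins; columns of the winning fit
    are ordered by descending mean proportion.  K = 1 is a valid single-
    profile model.
    """
    Y = beta.values
    m, n = Y.shape
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}]")
    if np.isnan(Y).all(axis=1).any():
        raise ValueError("all-missing CpG rows must be filtered out first")
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    if warm_start is not None:
        Mw = warm_start.values if isinstance(warm_start, MethylomeMatrix) else np.asarray(warm_start, dtype=float)
        if Mw.shape != (m, K):
            raise ValueError("warm start has wrong shape")
        starts.append(Mw.copy())
    if n_restarts >= 1:
        M0 = initialize_methylomes(beta, K, seed).values
        starts.append(M0)
        while len(starts) < n_restarts + (warm_start is not None):
            jitter = rng.uniform(-0.05, 0.05, size=M0.shape)
            starts.append(np.clip(M0 + jitter, 0.0, 1.0))
    if not starts and not extra_starts:
        raise ValueError("need at least one start (n_restarts >= 1 or a warm start)")
    for extra in extra_starts or []:
        starts.append(np.clip(np.asarray(extra, dtype=float), 0.0, 1.0))

    best: DeconvolutionFit | None = None
    for r, M in enumerate(starts):
        history: list[float] = []
        converged = False
        it = 0
        for it in range(1, n_iter + 1):
            W = _omega_step(Y, M)
            history.append(_rss(Y, M, W))
            M = _m_step(Y, W)
            history.append(_rss(Y, M, W))
            if len(history) >= 4:
                prev, cur = history[-4], history[-1]
                if prev - cur <= tol * max(prev, 1e-12):
                    converged = True
                    break
        rss = history[-1]
        if best is None or rss < best.rss - 1e-12:
            Mm = MethylomeMatrix(M, list(beta.cpg_ids), [f"type_{k+1}" for k in range(K)])
            Wm = ProportionMatrix(W, list(beta.specimen_ids), list(Mm.type_labels))
            best = DeconvolutionFit(Mm, Wm, rss, it, converged, r, history)

    # canonical column order: descending mean proportion
    order = np.argsort(-best.Omega.values.mean(axis=0), kind="stable")
    labels = [f"type_{k+1}" for k in range(K)]
    best.M = MethylomeMatrix(best.M.values[:, order], best.M.cpg_ids, labels)
    best.Omega = ProportionMatrix(best.Omega.values[:, order], best.Omega.specimen_ids, labels)
    return best


def fit_k_sequence(beta: BetaMatrix, K_values, n_iter: int = 25, n_restarts: int = 5,
                   seed: int = 0, tol: float = 1e-6) -> dict[int, DeconvolutionFit]:
    """Fit a chain of models over a K grid with nested warm starts.

    For each K beyond the smallest, an extra start duplicates the heaviest
    column of the previous best M (the new column can absorb a split of its
    proportions), which makes the best rss non-increasing in K.
    """
    fits: dict[int, DeconvolutionFit] = {}
    prev: DeconvolutionFit | None = None
    for K in sorted(K_values):
        extra = None
        if prev is not None and prev.M.K == K - 1:
            dup = np.column_stack([prev.M.values, prev.M.values[:, 0]])
            extra = [dup]
        fits[K] = deconvolve(beta, K, n_iter=n_iter, n_restarts=n_restarts,
                             seed=seed, tol=tol, extra_starts=extra)
        prev = fits[K]
    return fits


def project_to_reference(beta: BetaMatrix, reference: MethylomeMatrix) -> ProportionMatrix:
    """Project specimens onto known reference methylomes.

    Uses the CpGs common to both matrices and solves each specimen's
    sub-simplex weights against the reference.  Also usable column-wise on
    a fitted MethylomeMatrix (treat its columns as specimens) to obtain a
    mixing matrix.
    """
    ref_index = {c: i for i, c in enumerate(reference.cpg_ids)}
    shared = [(j, ref_index[c]) for j, c in enumerate(beta.cpg_ids) if c in ref_index]
    if not shared:
        raise ValueError("no CpGs shared between beta matrix and reference")
    bj = [s[0] for s in shared]
    rj = [s[1] for s in shared]
    Yb = beta.values[bj]
    A = reference.values[rj]
    n = Yb.shape[1]
    W = np.zeros((n, A.shape[1]))
    col_complete = ~np.isnan(Yb).any(axis=0)
    if col_complete.any():
        W[col_complete] = _qp.subsimplex_lsq_multi(A.T @ A, A.T @ Yb[:, col_complete]).T
    for i in np.flatnonzero(~col_complete):
        obs = ~np.isnan(Yb[:, i])
        W[i] = _qp.subsimplex_lsq(A[obs], Yb[obs, i])
    return ProportionMatrix(W, list(beta.specimen_ids), list(reference.type_labels))


def residualize_against_reference(M1: MethylomeMatrix, M0: MethylomeMatrix):
    """Express fitted methylomes in terms of a reference and residualize.

    Returns ``(Psi, residual)`` where Psi (K_ref x K_free, columns on the
    sub-simplex) holds the constrained projection of each column of M1 onto
    the columns of M0, and ``residual = M1 - M0 @ Psi`` (entries may be
    negative).  Requires identical CpG ordering.
    """
    if M1.cpg_ids != M0.cpg_ids:
        raise ValueError("M1 and M0 must share the same CpGs in the same order")
    fake = BetaMatrix(M1.values.copy(), list(M1.cpg_ids), list(M1.type_labels))
    proj = project_to_reference(fake, M0)
    Psi = MixingMatrix(proj.values.T, list(M0.type_labels), list(M1.type_labels))
    residual = M1.values - M0.values @ Psi.values
    return Psi, residual
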