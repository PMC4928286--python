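"""Small dense quadratic programs for constrained least squares.

The alternating deconvolution repeatedly solves two families of tiny
(K-dimensional, K <= ~12) strictly convex quadratic programs:

* box-constrained least squares  — one per CpG row, entries in [0, 1];
* sub-simplex least squares      — one per specimen, weights >= 0 with
  sum <= 1.

All subproblems within one half-step share the same design matrix, so the
solvers here work on the normal-equation form (Q = A'A, C = A'B) and solve
many right-hand sides at once by block principal pivoting, batching the
linear solves by active-set pattern.  A Murty single-exchange safeguard
guarantees finite termination; the rare column that still fails its KKT
check is polished with SLSQP.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

_TOL = 1e-9
_BACKUP_PATIENCE = 3

__all__ = [
    "box_lsq_multi",
    "subsimplex_lsq_multi",
    "box_lsq",
    "subsimplex_lsq",
    "kkt_residual_box",
    "kkt_residual_subsimplex",
]


def _grouped_solve(Q: np.ndarray, rhs_cols, free: np.ndarray) -> np.ndarray:
    """Solve Q[free][:, free] x = rhs for a batch of right-hand sides."""
    Qff = Q[np.ix_(free, free)]
    try:
        return np.linalg.solve(Qff, rhs_cols)
    except np.linalg.LinAlgError:
        # rank-deficient active set (e.g. duplicated methylome columns):
        # take the minimum-norm solution
        return np.linalg.lstsq(Qff, rhs_cols, rcond=None)[0]


def box_lsq_multi(Q: np.ndarray, C: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Minimise ``0.5 x'Qx - c'x`` s.t. ``0 <= x <= 1`` for every column c of C.

    Parameters
    ----------
    Q : (K, K) positive semi-definite Gram matrix shared by all problems.
    C : (K, R) one column per problem.

    Returns
    -------
    (K, R) array of solutions.
    """
    Q = np.asarray(Q, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    K, R = C.shape
    if max_iter is None:
        max_iter = 30 + 10 * K

    FREE, LO, HI = 0, 1, 2
    state = np.zeros((K, R), dtype=np.int8)
    x = np.zeros((K, R))
    alive = np.ones(R, dtype=bool)
    best_nviol = np.full(R, K + 2, dtype=np.int64)
    patience = np.full(R, _BACKUP_PATIENCE, dtype=np.int64)
    single = np.zeros(R, dtype=bool)
    pows = 3 ** np.arange(K, dtype=np.int64)

    for _ in range(max_iter):
        cols = np.flatnonzero(alive)
        if cols.size == 0:
            break
        # batched equality-constrained solves, grouped by active-set pattern
        keys = pows @ state[:, cols]
        order = np.argsort(keys, kind="stable")
        keys_sorted = keys[order]
        starts = np.flatnonzero(np.r_[True, np.diff(keys_sorted) != 0])
        for si, s0 in enumerate(starts):
            s1 = starts[si + 1] if si + 1 < len(starts) else len(order)
            grp = cols[order[s0:s1]]
            st = state[:, grp[0]]
            free = st == FREE
            hi = st == HI
            x[np.ix_(np.flatnonzero(hi), grp)] = 1.0
            x[np.ix_(np.flatnonzero(st == LO), grp)] = 0.0
            if free.any():
                rhs = C[np.ix_(np.flatnonzero(free), grp)]
                if hi.any():
                    rhs = rhs - Q[np.ix_(np.flatnonzero(free), np.flatnonzero(hi))].sum(
                        axis=1, keepdims=True
                    )
                x[np.ix_(np.flatnonzero(free), grp)] = _grouped_solve(Q, rhs, np.flatnonzero(free))

        g = Q @ x[:, cols] - C[:, cols]
        st = state[:, cols]
        xv = x[:, cols]
        v_lo = (st == FREE) & (xv < -_TOL)
        v_hi = (st == FREE) & (xv > 1.0 + _TOL)
        v_glo = (st == LO) & (g < -_TOL)
        v_ghi = (st == HI) & (g > _TOL)
        viol = v_lo | v_hi | v_glo | v_ghi
        nv = viol.sum(axis=0)

        done = nv == 0
        alive[cols[done]] = False
        rest = ~done
        if not rest.any():
            break
        rcols = cols[rest]
        improved = nv[rest] < best_nviol[rcols]
        best_nviol[rcols[improved]] = nv[rest][improved]
        patience[rcols[improved]] = _BACKUP_PATIENCE
        patience[rcols[~improved]] -= 1
        single[rcols] |= patience[rcols] < 0

        for j_local, j in zip(np.flatnonzero(rest), rcols):
            vl = viol[:, j_local]
            if single[j]:
                k = np.flatnonzero(vl)[-1]  # Murty: highest-index violation only
                vl = np.zeros(K, dtype=bool)
                vl[k] = True
            sj = state[:, j]
            to_lo = vl & v_lo[:, j_local]
            to_hi = vl & v_hi[:, j_local]
            to_free = vl & (v_glo[:, j_local] | v_ghi[:, j_local])
            sj[to_lo] = LO
            sj[to_hi] = HI
            sj[to_free] = FREE

    np.clip(x, 0.0, 1.0, out=x)
    # polish any stragglers that failed to converge
    bad = np.flatnonzero(alive)
    for j in bad:
        if kkt_residual_box(Q, C[:, j], x[:, j]) > 1e-7:
            x[:, j] = _slsqp_box(Q, C[:, j], x[:, j])
    return x


def subsimplex_lsq_multi(Q: np.ndarray, C: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Minimise ``0.5 w'Qw - c'w`` s.t. ``w >= 0``, ``sum(w) <= 1`` per column of C."""
    Q = np.asarray(Q, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    K, R = C.shape
    if max_iter is None:
        max_iter = 30 + 10 * K

    FREE, LO = 0, 1
    state = np.zeros((K, R), dtype=np.int8)
    sum_active = np.zeros(R, dtype=bool)
    x = np.zeros((K, R))
    lam = np.zeros(R)
    alive = np.ones(R, dtype=bool)
    best_nviol = np.full(R, K + 3, dtype=np.int64)
    patience = np.full(R, _BACKUP_PATIENCE, dtype=np.int64)
    single = np.zeros(R, dtype=bool)
    pows = 2 ** np.arange(K, dtype=np.int64)

    for _ in range(max_iter):
        cols = np.flatnonzero(alive)
        if cols.size == 0:
            break
        # columns where the sum constraint is active but no variable is free
        # cannot satisfy sum == 1; release the constraint
        nfree = (state[:, cols] == FREE).sum(axis=0)
        fix = sum_active[cols] & (nfree == 0)
        sum_active[cols[fix]] = False

        keys = pows @ state[:, cols] + (1 << K) * sum_active[cols].astype(np.int64)
        order = np.argsort(keys, kind="stable")
        keys_sorted = keys[order]
        starts = np.flatnonzero(np.r_[True, np.diff(keys_sorted) != 0])
        for si, s0 in enumerate(starts):
            s1 = starts[si + 1] if si + 1 < len(starts) else len(order)
            grp = cols[order[s0:s1]]
            st = state[:, grp[0]]
            act = sum_active[grp[0]]
            free_idx = np.flatnonzero(st == FREE)
            lo_idx = np.flatnonzero(st == LO)
            x[np.ix_(lo_idx, grp)] = 0.0
            lam[grp] = 0.0
            if free_idx.size == 0:
                continue
            if not act:
                rhs = C[np.ix_(free_idx, grp)]
                x[np.ix_(free_idx, grp)] = _grouped_solve(Q, rhs, free_idx)
            else:
                f = free_idx.size
                kkt = np.empty((f + 1, f + 1))
                kkt[:f, :f] = Q[np.ix_(free_idx, free_idx)]
                kkt[:f, f] = 1.0
                kkt[f, :f] = 1.0
                kkt[f, f] = 0.0
                rhs = np.empty((f + 1, grp.size))
                rhs[:f] = C[np.ix_(free_idx, grp)]
                rhs[f] = 1.0
                try:
                    sol = np.linalg.solve(kkt, rhs)
                except np.linalg.LinAlgError:
                    sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
                x[np.ix_(free_idx, grp)] = sol[:f]
                lam[grp] = sol[f]

        xv = x[:, cols]
        g = Q @ xv - C[:, cols]
        st = state[:, cols]
        v_neg = (st == FREE) & (xv < -_TOL)
        colsum = np.where(st == FREE, xv, 0.0).sum(axis=0)
        v_sum = (~sum_active[cols]) & (colsum > 1.0 + _TOL)
        v_lam = sum_active[cols] & (lam[cols] < -_TOL)
        v_dual = (st == LO) & (g + lam[cols][None, :] < -_TOL)
        viol_var = v_neg | v_dual
        nv = viol_var.sum(axis=0) + v_sum + v_lam

        done = nv == 0
        alive[cols[done]] = False
        rest = ~done
        if not rest.any():
            break
        rcols = cols[rest]
        improved = nv[rest] < best_nviol[rcols]
        best_nviol[rcols[improved]] = nv[rest][improved]
        patience[rcols[improved]] = _BACKUP_PATIENCE
        patience[rcols[~improved]] -= 1
        single[rcols] |= patience[rcols] < 0

        for j_local, j in zip(np.flatnonzero(rest), rcols):
            choices = []  # (index-for-Murty, kind, var)
            for k in np.flatnonzero(viol_var[:, j_local]):
                kind = "to_lo" if v_neg[k, j_local] else "to_free"
                choices.append((k, kind, k))
            if v_sum[j_local]:
                choices.append((K, "sum_on", -1))
            if v_lam[j_local]:
                choices.append((K, "sum_off", -1))
            if single[j]:
                choices = [max(choices, key=lambda t: t[0])]
            for _, kind, k in choices:
                if kind == "to_lo":
                    state[k, j] = LO
                elif kind == "to_free":
                    state[k, j] = FREE
                elif kind == "sum_on":
                    sum_active[j] = True
                else:
                    sum_active[j] = False

    np.clip(x, 0.0, None, out=x)
    # exact re-projection of sums marginally above 1 from fp round-off
    s = x.sum(axis=0)
    over = s > 1.0
    if over.any():
        x[:, over] /= np.maximum(s[over], 1.0)[None, :]
    bad = np.flatnonzero(alive)
    for j in bad:
        if kkt_residual_subsimplex(Q, C[:, j], x[:, j]) > 1e-7:
            x[:, j] = _slsqp_subsimplex(Q, C[:, j], x[:, j])
    return x


def box_lsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least squares ``min ||Ax - b||`` with ``0 <= x <= 1`` (single system)."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    return box_lsq_multi(A.T @ A, (A.T @ b)[:, None])[:, 0]


def subsimplex_lsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least squares ``min ||Aw - b||`` with ``w >= 0``, ``sum(w) <= 1``."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    return subsimplex_lsq_multi(A.T @ A, (A.T @ b)[:, None])[:, 0]


def kkt_residual_box(Q: np.ndarray, c: np.ndarray, x: np.ndarray, tol: float = 1e-8) -> float:
    """Max KKT violation of x for the box problem (0 = certified optimum)."""
    g = Q @ x - c
    r = 0.0
    r = max(r, float(np.max(-x, initial=0.0)), float(np.max(x - 1.0, initial=0.0)))
    interior = (x > tol) & (x < 1.0 - tol)
    if interior.any():
        r = max(r, float(np.abs(g[interior]).max()))
    lo = x <= tol
    if lo.any():
        r = max(r, float(np.max(-g[lo], initial=0.0)))
    hi = x >= 1.0 - tol
    if hi.any():
        r = max(r, float(np.max(g[hi], initial=0.0)))
    return r


def kkt_residual_subsimplex(Q: np.ndarray, c: np.ndarray, x: np.ndarray, tol: float = 1e-8) -> float:
    """Max KKT violation of x for the sub-simplex problem."""
    g = Q @ x - c
    r = max(float(np.max(-x, initial=0.0)), float(x.sum() - 1.0))
    lam = 0.0
    if x.sum() >= 1.0 - tol:
        free = x > tol
        if free.any():
            lam = max(0.0, float(-g[free].mean()))
    free = x > tol
    if free.any():
        r = max(r, float(np.abs(g[free] + lam).max()))
    at_zero = ~free
    if at_zero.any():
        r = max(r, float(np.max(-(g[at_zero] + lam), initial=0.0)))
    return r


def _slsqp_box(Q, c, x0):
    res = minimize(
        lambda x: 0.5 * x @ Q @ x - c @ x,
        np.clip(x0, 0.0, 1.0),
        jac=lambda x: Q @ x - c,
        bounds=[(0.0, 1.0)] * len(c),
        method="SLSQP",
        options={"maxiter": 300, "ftol": 1e-14},
    )
    return np.clip(res.x, 0.0, 1.0)


def _slsqp_subsimplex(Q, c, x0):
    x0 = np.clip(x0, 0.0, None)
    if x0.sum() > 1.0:
        x0 = x0 / x0.sum()
    res = minimize(
        lambda x: 0.5 * x @ Q @ x - c @ x,
        x0,
        jac=lambda x: Q @ x - c,
        bounds=[(0.0, 1.0)] * len(c),
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(), "jac": lambda x: -np.ones_like(x)}],
        method="SLSQP",
        options={"maxiter": 300, "ftol": 1e-14},
    )
    x = np.clip(res.x, 0.0, None)
    if x.sum() > 1.0:
        x = x / x.sum()
    return x
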