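"""Phenotype association and mediation by cell composition.

Two complementary analyses of a fitted proportion matrix Omega:

* an omnibus permutation test of each covariate against Omega, averaged
  over the whole K grid so the conclusion does not hinge on one choice of
  K — each proportion column is modelled with a quasi-binomial GLM (logit
  link, variance proportional to mu(1-mu)) and the statistic accumulates
  the quasi-deviance explained by the covariate given the others;

* CpG-wise regression of M-values on the phenotype design with and without
  the Omega columns, with empirical-Bayes variance moderation, followed by
  Storey pi0 estimation.  A rise in pi0 (the estimated proportion of null
  CpGs) after adjusting for Omega quantifies how much of the epigenome-wide
  signal is mediated by cell composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .deconvolution import DeconvolutionFit, ProportionMatrix, fit_k_sequence
from .io import BetaMatrix, CovariateTable

__all__ = [
    "QuasiBinomialFit",
    "PermutationResult",
    "Pi0Result",
    "CpGRegressionResult",
    "fit_quasibinomial",
    "permutation_test",
    "mvalue_transform",
    "adjusted_cpg_regression",
    "estimate_pi0",
    "qvalues",
    "mediation_comparison",
]


# ---------------------------------------------------------------------------
# quasi-binomial GLM

@dataclass
class QuasiBinomialFit:
    coef: np.ndarray
    null_deviance: float
    deviance: float
    dispersion: float
    n_iter: int
    converged: bool
    degenerate: bool = False


def _qb_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * (special.xlogy(y, y) - special.xlogy(y, mu)
                        + special.xlogy(1 - y, 1 - y) - special.xlogy(1 - y, 1 - mu)).sum())


def fit_quasibinomial(y: np.ndarray, X: np.ndarray, max_iter: int = 50,
                      tol: float = 1e-10) -> QuasiBinomialFit:
    """IRLS fit of proportions in [0, 1] on a design matrix.

    Logit link with variance proportional to mu(1-mu); the dispersion is
    the Pearson chi-square over residual degrees of freedom.  A column with
    no variation returns a flagged degenerate fit explaining no deviance.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if np.ptp(y) == 0.0:
        coef = np.zeros(p)
        mu0 = float(np.clip(y[0], 1e-12, 1 - 1e-12))
        coef[0] = special.logit(mu0) if np.allclose(X[:, 0], 1.0) else 0.0
        return QuasiBinomialFit(coef, 0.0, 0.0, 0.0, 0, True, degenerate=True)

    mu = np.clip((y + y.mean()) / 2.0, 1e-6, 1 - 1e-6)
    eta = special.logit(mu)
    dev = _qb_deviance(y, mu)
    coef = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ coef
        mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
        dev_new = _qb_deviance(y, mu)
        if abs(dev - dev_new) <= tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    mu_null = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    null_dev = _qb_deviance(y, np.full_like(y, mu_null))
    pearson = float((((y - mu) ** 2) / (mu * (1 - mu))).sum())
    dispersion = pearson / max(n - p, 1)
    return QuasiBinomialFit(coef, null_dev, dev, dispersion, it, converged)


# ---------------------------------------------------------------------------
# omnibus permutation test

@dataclass
class PermutationResult:
    covariate: str
    observed_statistic: float
    n_permutations: int
    p_value: float
    per_K_statistics: dict[int, float] = field(default_factory=dict)


def _covariate_stat(omegas: dict[int, np.ndarray], X_full: np.ndarray,
                    target_cols: list[int], reduced_dev: dict[int, np.ndarray]) -> tuple[float, dict[int, float]]:
    """T = mean over the K grid of D_K / K, where D_K sums (over proportion
    columns) the quasi-deviance explained by the target covariate given the
    other covariates.  K = 1 contributes 0."""
    X_red_cols = [c for c in range(X_full.shape[1]) if c not in target_cols]
    per_K: dict[int, float] = {}
    for K, W in omegas.items():
        if K == 1:
            per_K[1] = 0.0
            continue
        D = 0.0
        for k in range(W.shape[1]):
            full = fit_quasibinomial(W[:, k], X_full)
            D += max(reduced_dev[K][k] - full.deviance, 0.0)
        per_K[K] = D / K
    T = float(np.mean(list(per_K.values())))
    return T, per_K


def permutation_test(beta: BetaMatrix | None, design: CovariateTable, covariate: str,
                     K_max: int = 10, n_permutations: int = 1000, seed: int = 0,
                     fits: dict[int, DeconvolutionFit] | None = None,
                     fit_seed: int = 0, **fit_kwargs) -> PermutationResult:
    """Omnibus permutation test of one covariate against cell proportions.

    Associations are assessed over the whole grid K in {1, ..., K_max} to
    avoid conditioning conclusions on a single K; the covariate's values
    are shuffled across specimens (Omega fixed) and the add-one rule gives
    the tail probability.  Precomputed ``fits`` (K -> DeconvolutionFit) are
    reused when supplied; otherwise the grid is fit from ``beta``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if covariate not in design.data.columns:
        raise KeyError(f"covariate {covariate!r} not in design")
    col = design.data[covariate]
    vals = np.asarray(col.cat.codes if isinstance(col.dtype, pd.CategoricalDtype) else col)
    if np.ptp(vals.astype(float)) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")

    if fits is None:
        if beta is None:
            raise ValueError("either beta or precomputed fits are required")
        K_grid = list(range(1, K_max + 1))
        fits = fit_k_sequence(beta, [k for k in K_grid if k >= 2], seed=fit_seed, **fit_kwargs)
    else:
        K_grid = sorted(set(fits) | {1})
    omegas = {K: fits[K].Omega.values for K in fits}
    omegas[1] = np.ones((len(design.data), 1))  # placeholder; K=1 contributes 0

    X_full, names, groups = design.design_matrix()
    target_cols = groups[covariate]

    # reduced models do not involve the permuted covariate: fit once
    X_red = X_full[:, [c for c in range(X_full.shape[1]) if c not in target_cols]]
    reduced_dev = {}
    for K, W in omegas.items():
        if K == 1:
            continue
        reduced_dev[K] = np.array([fit_quasibinomial(W[:, k], X_red).deviance
                                   for k in range(W.shape[1])])

    T_obs, per_K = _covariate_stat(omegas, X_full, target_cols, reduced_dev)

    # permuting the covariate's raw values equals permuting the rows of the
    # design columns it generates; the other columns are untouched
    rng = np.random.default_rng(seed)
    count = 0
    Xp = X_full.copy()
    for _ in range(n_permutations):
        perm = rng.permutation(X_full.shape[0])
        Xp[:, target_cols] = X_full[perm][:, target_cols]
        T_perm, _ = _covariate_stat(omegas, Xp, target_cols, reduced_dev)
        if T_perm >= T_obs:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return PermutationResult(covariate, T_obs, n_permutations, p, per_K)


# ---------------------------------------------------------------------------
# CpG-wise regression with moderated statistics

def mvalue_transform(beta_values: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """log2(beta / (1 - beta)) after clipping beta into [eps, 1 - eps]."""
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    b = np.clip(np.asarray(beta_values, dtype=float), epsilon, 1.0 - epsilon)
    return np.log2(b / (1.0 - b))


def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y (Newton on the limma parametrization)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _moderate_variances(s2: np.ndarray, d: float):
    """Empirical-Bayes shrinkage of residual variances.

    Method of moments on log residual variances: the excess spread of
    log(s^2) beyond its chi-square sampling noise determines the prior
    degrees of freedom d0; the prior variance s0^2 centres the shrinkage.
    When no excess spread is observed the variances are left unshrunk
    (d0 = inf with s0^2 at the geometric mean, so equal-variance input
    reproduces ordinary t statistics exactly).
    """
    s2 = np.maximum(s2, 1e-300)
    e = np.log(s2)
    if len(s2) < 2:
        warnings.warn("a single CpG: no pooling possible, using ordinary t",
                      RuntimeWarning)
        return s2.copy(), 0.0, float(s2[0])
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 1e-10:
        s0_2 = float(np.exp(e.mean()))
        return np.full_like(s2, s0_2), np.inf, s0_2
    d0 = 2.0 * _trigamma_inverse(float(evar))
    s0_2 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
                        - special.digamma(d / 2.0) + np.log(d / 2.0)))
    s2_mod = (d0 * s0_2 + d * s2) / (d0 + d)
    return s2_mod, d0, s0_2


@dataclass
class CpGRegressionResult:
    cpg_ids: list[str]
    coef_names: list[str]
    coef: np.ndarray                      # (m, p)
    t: np.ndarray                         # (m, p) moderated t
    p: np.ndarray                         # (m, p) per-column p-values
    covariate_p: dict[str, np.ndarray]    # per-covariate (partial F) p-values
    omega_F: np.ndarray | None            # omnibus Omega F statistic
    omega_p: np.ndarray | None
    s2: np.ndarray
    s2_mod: np.ndarray
    d_resid: float
    d0: float
    s0_2: float


def adjusted_cpg_regression(beta: BetaMatrix, design: CovariateTable,
                            omega: ProportionMatrix | None = None,
                            covariates: list[str] | None = None,
                            epsilon: float = 1e-6) -> CpGRegressionResult:
    """Per-CpG OLS of M-values on [X, Omega] with moderated statistics.

    When Omega is supplied its last canonical column is dropped (rows near
    the simplex make the full set collinear with the intercept).  Variances
    are moderated empirical-Bayes style and each coefficient gets a
    moderated t on d0 + d degrees of freedom; each covariate additionally
    gets a partial (moderated) F across its design columns, and the Omega
    block gets an omnibus F.
    """
    X, names, groups = design.design_matrix(covariates)
    omega_cols: list[int] = []
    if omega is not None:
        Wo = omega.values[:, :-1] if omega.K > 1 else omega.values
        keep = [k for k in range(Wo.shape[1])]
        omega_cols = list(range(X.shape[1], X.shape[1] + len(keep)))
        X = np.column_stack([X, Wo])
        names = names + [f"omega[{omega.type_labels[k]}]" for k in keep]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design with Omega columns is rank deficient")

    Y = mvalue_transform(beta.values, epsilon)
    if np.isnan(Y).any():
        raise ValueError("CpG regression requires complete data; filter or impute first")
    n, p = X.shape
    d = n - p
    if d <= 0:
        raise ValueError("no residual degrees of freedom")

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = Y @ X @ XtX_inv                       # (m, p)
    resid = Y - B @ X.T
    s2 = (resid * resid).sum(axis=1) / d
    s2_mod, d0, s0_2 = _moderate_variances(s2, d)
    df_total = d0 + d if np.isfinite(d0) else np.inf

    se = np.sqrt(np.outer(s2_mod, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df=min(df_total, 1e12))

    def _block_F(cols: list[int]) -> tuple[np.ndarray, np.ndarray]:
        V = XtX_inv[np.ix_(cols, cols)]
        Vinv = np.linalg.inv(V)
        Bc = B[:, cols]
        q = len(cols)
        F = np.einsum("ij,jk,ik->i", Bc, Vinv, Bc) / (q * s2_mod)
        return F, stats.f.sf(F, q, min(df_total, 1e12))

    covariate_p: dict[str, np.ndarray] = {}
    for cov, cols in groups.items():
        covariate_p[cov] = _block_F(cols)[1]
    omega_F = omega_p = None
    if omega_cols:
        omega_F, omega_p = _block_F(omega_cols)

    return CpGRegressionResult(list(beta.cpg_ids), names, B, t, pvals, covariate_p,
                               omega_F, omega_p, s2, s2_mod, float(d), float(d0), s0_2)


# ---------------------------------------------------------------------------
# pi0 / q-values

@dataclass
class Pi0Result:
    covariate: str
    model: str
    p_values: np.ndarray
    pi0: float
    lambdas: np.ndarray = field(default=None, repr=False)
    pi0_lambda: np.ndarray = field(default=None, repr=False)


def estimate_pi0(p_values, covariate: str = "", model: str = "") -> Pi0Result:
    """Storey estimator of the proportion of null hypotheses.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid
    lambda = 0.05, 0.10, ..., 0.95; a cubic polynomial smooth of the
    profile is extrapolated to lambda -> 1 and clamped to [0, 1].
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.clip(np.polyval(coeffs, 1.0), 0.0, 1.0))
    return Pi0Result(covariate, model, p, pi0, lambdas, pi0_lambda)


def qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Step-up q-values with the estimated pi0 factor."""
    p = np.asarray(list(p_values), dtype=float)
    if pi0 is None:
        pi0 = estimate_pi0(p).pi0
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * pi0 / (np.arange(m) + 1.0)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def mediation_comparison(beta: BetaMatrix, design: CovariateTable,
                         omega_star: ProportionMatrix,
                         covariates: list[str] | None = None):
    """Paired pi0 before/after adjusting for cell proportions.

    Fits the CpG-wise regression with the phenotype design alone (the
    K = 1 model) and with the Omega columns of the K* fit added, and
    returns per-covariate (pi0_unadjusted, pi0_adjusted) plus the pi0 of
    the omnibus Omega association under the adjusted model.
    """
    unadj = adjusted_cpg_regression(beta, design, omega=None, covariates=covariates)
    adj = adjusted_cpg_regression(beta, design, omega=omega_star, covariates=covariates)
    rows = []
    for cov in unadj.covariate_p:
        rows.append({
            "covariate": cov,
            "pi0_unadjusted": estimate_pi0(unadj.covariate_p[cov]).pi0,
            "pi0_adjusted": estimate_pi0(adj.covariate_p[cov]).pi0,
        })
    omega_pi0 = estimate_pi0(adj.omega_p).pi0 if adj.omega_p is not None else np.nan
    out = pd.DataFrame(rows)
    out.attrs["pi0_omega"] = omega_pi0
    return out
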