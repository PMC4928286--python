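"""Quasi-binomial GLM, permutation tests, moderated regression and pi0."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from methmix import (CovariateTable, ProportionMatrix, adjusted_cpg_regression,
                     deconvolve, estimate_pi0, fit_k_sequence, fit_quasibinomial,
                     mediation_comparison, mvalue_transform, permutation_test,
                     qvalues)

from conftest import covariate_table, make_beta


# --- quasi-binomial GLM -----------------------------------------------------

def test_constant_proportions_no_deviance_explained():
    X = np.column_stack([np.ones(20), np.arange(20.0)])
    f = fit_quasibinomial(np.full(20, 0.5), X)
    assert f.degenerate
    assert f.coef[1] == 0.0
    assert f.null_deviance - f.deviance == 0.0


def test_two_group_closed_form():
    g = np.repeat([0.0, 1.0], 10)
    X = np.column_stack([np.ones(20), g])
    p0, p1 = 0.3, 0.7
    y = np.where(g == 0, p0, p1)
    f = fit_quasibinomial(y, X)
    assert abs(f.coef[0] - special.logit(p0)) < 1e-6
    assert abs(f.coef[1] - (special.logit(p1) - special.logit(p0))) < 1e-6


def test_matches_statsmodels_glm():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(0)
    n = 50
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    mu = special.expit(-0.4 + 0.9 * x)
    y = np.clip(mu + rng.normal(0, 0.05, n), 1e-3, 1 - 1e-3)
    f = fit_quasibinomial(y, X)
    g = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(f.coef, g.params, atol=1e-6)
    assert abs(f.deviance - g.deviance) < 1e-8
    assert abs(f.dispersion - g.pearson_chi2 / (n - 2)) < 1e-8


def test_rank_deficient_design_rejected():
    X = np.column_stack([np.ones(10), np.ones(10)])
    with pytest.raises(ValueError):
        fit_quasibinomial(np.linspace(0.2, 0.8, 10), X)


# --- permutation test -------------------------------------------------------

def _fits_for(truth, Ks=(2, 3)):
    return fit_k_sequence(truth.Y, list(Ks), n_iter=15, n_restarts=1, seed=0)


def test_planted_association_detected(mediated_truth):
    design = covariate_table(mediated_truth)
    fits = _fits_for(mediated_truth)
    res = permutation_test(None, design, "group", n_permutations=199, seed=1, fits=fits)
    assert res.p_value <= 0.01
    assert res.per_K_statistics[1] == 0.0
    assert set(res.per_K_statistics) == {1, 2, 3}


def test_null_covariate_not_significant(small_truth):
    rng = np.random.default_rng(9)
    design = covariate_table(small_truth, extra={"noise": rng.normal(size=40)})
    fits = _fits_for(small_truth)
    res = permutation_test(None, design, "noise", n_permutations=99, seed=2, fits=fits)
    assert res.p_value > 0.05
    assert 0 < res.p_value <= 1


def test_permutation_p_uses_add_one_rule(mediated_truth):
    design = covariate_table(mediated_truth)
    fits = _fits_for(mediated_truth, Ks=(2,))
    res = permutation_test(None, design, "group", n_permutations=19, seed=0, fits=fits)
    assert res.p_value >= 1.0 / 20.0


def test_constant_covariate_rejected(small_truth):
    design = covariate_table(small_truth, extra={"flat": np.zeros(40)})
    with pytest.raises(ValueError):
        permutation_test(None, design, "flat", fits=_fits_for(small_truth))


# --- M-values ---------------------------------------------------------------

def test_mvalue_examples():
    assert mvalue_transform(0.5) == 0.0
    assert abs(mvalue_transform(0.8) - 2.0) < 1e-12
    eps = 1e-6
    assert abs(mvalue_transform(0.0, eps) - np.log2(eps / (1 - eps))) < 1e-12


# --- moderated CpG regression -----------------------------------------------

def _two_group_data(m=300, n=30, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    g = np.repeat([0.0, 1.0], n // 2)
    mvals = rng.normal(0, 1, (m, n)) + effect * g[None, :]
    beta_vals = 1.0 / (1.0 + 2.0 ** (-mvals))
    truth_beta = make_beta(beta_vals)
    design = CovariateTable(pd.DataFrame({"group": g},
                                         index=truth_beta.specimen_ids))
    return truth_beta, design, g


def test_two_group_matches_classic_t_test():
    beta, design, g = _two_group_data(seed=2)
    res = adjusted_cpg_regression(beta, design)
    Y = mvalue_transform(beta.values)
    t_ref, _ = stats.ttest_ind(Y[:, g == 1].T, Y[:, g == 0].T, equal_var=True)
    # before moderation: the OLS slope t equals the pooled two-sample t
    t_ols = res.coef[:, 1] / np.sqrt(res.s2 * (2.0 / (len(g) // 2)) / 1.0)
    np.testing.assert_allclose(t_ols, t_ref, atol=1e-8)


def test_exact_equal_variances_keep_t_unchanged():
    # construct rows with *identical* residual variance by scaling residuals
    rng = np.random.default_rng(3)
    n, m = 16, 40
    g = np.repeat([0.0, 1.0], n // 2)
    X = np.column_stack([np.ones(n), g])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    R = rng.normal(0, 1, (m, n)) @ (np.eye(n) - H)  # residual space
    R /= np.sqrt((R ** 2).sum(axis=1, keepdims=True))  # equal RSS
    mvals = 0.3 * g[None, :] + R
    beta = make_beta(1.0 / (1.0 + 2.0 ** (-mvals)))
    design = CovariateTable(pd.DataFrame({"group": g}, index=beta.specimen_ids))
    res = adjusted_cpg_regression(beta, design)
    assert np.isinf(res.d0)
    t_ord = res.coef[:, 1] / np.sqrt(res.s2 * np.linalg.inv(X.T @ X)[1, 1])
    np.testing.assert_allclose(res.t[:, 1], t_ord, rtol=1e-6)


def test_null_moderated_pvalues_uniform():
    beta, design, g = _two_group_data(m=2000, n=40, seed=4)
    res = adjusted_cpg_regression(beta, design)
    p = res.covariate_p["group"]
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_single_cpg_warns_and_degenerates():
    beta, design, g = _two_group_data(m=1, seed=5)
    with pytest.warns(RuntimeWarning):
        res = adjusted_cpg_regression(beta, design)
    assert res.d0 == 0.0


# --- pi0 / q-values ---------------------------------------------------------

def test_pi0_uniform_grid_near_one():
    p = (np.arange(1000) + 1) / 1000.0
    assert 0.95 <= estimate_pi0(p).pi0 <= 1.0


def test_pi0_mixture_recovers_null_fraction():
    rng = np.random.default_rng(6)
    p = np.concatenate([rng.uniform(0, 1, 8000), rng.beta(0.05, 1, 2000)])
    assert 0.70 <= estimate_pi0(p).pi0 <= 0.90


def test_pi0_all_ones_is_one():
    assert estimate_pi0(np.ones(200)).pi0 == 1.0


def test_pi0_permutation_invariant():
    rng = np.random.default_rng(7)
    p = rng.uniform(0, 1, 500)
    assert estimate_pi0(p).pi0 == estimate_pi0(p[::-1]).pi0


def test_pi0_input_validation():
    with pytest.raises(ValueError):
        estimate_pi0([])
    with pytest.raises(ValueError):
        estimate_pi0([0.5, 1.2])


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(8)
    p = rng.uniform(0, 1, 300)
    q = qvalues(p, pi0=0.8)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q >= 0).all() and (q <= 1).all()


# --- mediation --------------------------------------------------------------

def test_zero_omega_column_does_not_change_pi0(small_truth):
    # adjusting by [w1, w2, 0] equals adjusting by [w1, w2]: the all-zero
    # column lands last in canonical order and is the one dropped
    rng = np.random.default_rng(10)
    x = rng.normal(size=40)
    w = rng.dirichlet((2, 2), size=40) * rng.uniform(0.6, 0.95, size=(40, 1))
    ids = small_truth.Y.specimen_ids
    design_a = covariate_table(small_truth, extra={"x": x})
    omega_a = ProportionMatrix(np.column_stack([w, np.zeros(40)]), ids, ["t1", "t2", "t3"])
    med_a = mediation_comparison(small_truth.Y, design_a, omega_a, covariates=["x"])
    design_b = covariate_table(small_truth,
                               extra={"x": x, "w1": w[:, 0], "w2": w[:, 1]})
    res_b = adjusted_cpg_regression(small_truth.Y, design_b,
                                    covariates=["x", "w1", "w2"])
    pi0_b = estimate_pi0(res_b.covariate_p["x"]).pi0
    assert med_a["pi0_adjusted"][0] == pi0_b


def test_full_mediation_raises_pi0(mediated_truth):
    design = covariate_table(mediated_truth)
    fit = deconvolve(mediated_truth.Y, 3, n_iter=50, n_restarts=2, seed=0)
    med = mediation_comparison(mediated_truth.Y, design, fit.Omega)
    gap = med["pi0_adjusted"][0] - med["pi0_unadjusted"][0]
    assert gap > 0.2
    assert med.attrs["pi0_omega"] < 0.2
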