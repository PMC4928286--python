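"""Constrained factorization: half-step solvers, full fits, projections."""

import numpy as np
import pytest

from methmix import (BetaMatrix, MethylomeMatrix, deconvolve, fit_k_sequence,
                     initialize_methylomes, match_columns, project_to_reference,
                     residualize_against_reference, solve_methylome_row,
                     solve_proportions)

from conftest import anchored_instance, make_beta


# --- initialization ---------------------------------------------------------

def test_init_block_structure_recovers_profiles():
    p1, p2 = np.full(30, 0.2), np.full(30, 0.8)
    Y = np.column_stack([p1] * 3 + [p2] * 4)
    M = initialize_methylomes(make_beta(Y), K=2)
    got = {tuple(np.round(M.values[:, k], 6)) for k in range(2)}
    assert got == {tuple(p1), tuple(p2)}


def test_init_k1_is_row_means():
    rng = np.random.default_rng(0)
    Y = rng.uniform(0, 1, (40, 6))
    Y[3, 2] = np.nan
    M = initialize_methylomes(make_beta(Y), K=1)
    np.testing.assert_allclose(M.values[:, 0], np.nanmean(Y, axis=1))


def test_init_means_within_row_range():
    rng = np.random.default_rng(1)
    Y = rng.uniform(0, 1, (200, 20))
    M = initialize_methylomes(make_beta(Y), K=4)
    lo, hi = Y.min(axis=1), Y.max(axis=1)
    assert (M.values >= lo[:, None] - 1e-12).all()
    assert (M.values <= hi[:, None] + 1e-12).all()


def test_init_errors():
    Y = np.tile(np.full((5, 1), 0.5), (1, 4))
    with pytest.raises(ValueError):
        initialize_methylomes(make_beta(Y), K=5)  # K > n
    with pytest.raises(ValueError):
        initialize_methylomes(make_beta(Y), K=2)  # identical profiles


# --- half-step solvers ------------------------------------------------------

def test_proportions_pure_column_gets_unit_weight():
    rng = np.random.default_rng(2)
    M = rng.uniform(0, 1, (50, 3))
    w = solve_proportions(M[:, 1], M)
    np.testing.assert_allclose(w, [0, 1, 0], atol=1e-7)


def test_proportions_sum_constraint_clips_scale():
    M = np.array([[0.5], [0.0]])
    y = np.array([1.0, 0.0])
    w = solve_proportions(y, M)  # unconstrained optimum 2, clipped to the simplex
    np.testing.assert_allclose(w, [1.0], atol=1e-10)


def test_proportions_rank_deficient_warns():
    M = np.column_stack([np.full(10, 0.5), np.full(10, 0.5)])
    with pytest.warns(RuntimeWarning):
        w = solve_proportions(np.full(10, 0.4), M)
    assert w.sum() <= 1 + 1e-8


def test_methylome_row_pure_specimens_gives_type_means():
    # each specimen is a pure type: the problem separates by type
    Omega = np.repeat(np.eye(3), 4, axis=0)
    rng = np.random.default_rng(3)
    y = rng.uniform(0, 1, 12)
    mu = solve_methylome_row(y, Omega)
    expect = [y[Omega[:, k] == 1].mean() for k in range(3)]
    np.testing.assert_allclose(mu, expect, atol=1e-9)


def test_methylome_row_interior_solution_unchanged():
    rng = np.random.default_rng(4)
    Omega = rng.dirichlet((2, 2), size=20)
    mu_true = np.array([0.4, 0.6])
    y = Omega @ mu_true
    mu = solve_methylome_row(y, Omega)
    np.testing.assert_allclose(mu, mu_true, atol=1e-8)


def test_half_steps_ignore_missing_entries():
    rng = np.random.default_rng(5)
    M = rng.uniform(0, 1, (30, 2))
    w_true = np.array([0.3, 0.6])
    y = M @ w_true
    y[5] = np.nan
    np.testing.assert_allclose(solve_proportions(y, M), w_true, atol=1e-8)


# --- full fits --------------------------------------------------------------

def test_rank_one_exact_fit():
    v = np.linspace(0.1, 0.9, 25)
    Y = np.tile(v[:, None], (1, 6))
    fit = deconvolve(make_beta(Y), K=1, n_iter=10, n_restarts=1)
    assert fit.rss < 1e-20
    np.testing.assert_allclose(fit.M.values[:, 0], v, atol=1e-10)
    np.testing.assert_allclose(fit.Omega.values[:, 0], 1.0, atol=1e-10)


def test_all_zero_beta_degenerates_to_zero():
    Y = np.zeros((10, 5))
    fit = deconvolve(make_beta(Y), K=1, n_iter=5, n_restarts=1)
    assert fit.rss == 0.0
    np.testing.assert_array_equal(fit.M.values, 0.0)
    np.testing.assert_array_equal(fit.Omega.values, 0.0)


def test_noiseless_anchored_recovery():
    beta, M_true, W_true = anchored_instance(seed=3)
    fit = deconvolve(beta, K=3, n_iter=300, n_restarts=3, seed=0)
    perm, rmse = match_columns(fit.M, MethylomeMatrix(M_true, beta.cpg_ids, ["a", "b", "c"]))
    assert np.abs(fit.M.values[:, perm] - M_true).max() < 0.02
    assert np.abs(fit.Omega.values[:, perm] - W_true).max() < 0.02


def test_rss_history_non_increasing(small_truth):
    fit = deconvolve(small_truth.Y, K=3, n_iter=15, n_restarts=2, seed=0)
    h = np.array(fit.rss_history)
    assert (np.diff(h) <= 1e-7 * np.maximum(h[:-1], 1)).all()
    assert fit.rss >= 0
    assert fit.M.values.min() >= 0 and fit.M.values.max() <= 1
    sums = fit.Omega.values.sum(axis=1)
    assert fit.Omega.values.min() >= 0 and (sums <= 1 + 1e-8).all()


def test_nested_k_rss_non_increasing(small_truth):
    fits = fit_k_sequence(small_truth.Y, [2, 3, 4], n_iter=15, n_restarts=1, seed=0)
    assert fits[3].rss <= fits[2].rss + 1e-8
    assert fits[4].rss <= fits[3].rss + 1e-8


def test_permutation_equivariance_on_block_input():
    # unequal blocks of identical specimens: the initializer is
    # permutation-stable, so permuting specimens permutes Omega rows
    p1, p2 = np.linspace(0.1, 0.5, 30), np.linspace(0.9, 0.4, 30)
    Y = np.column_stack([p1] * 4 + [p2] * 2)
    beta = make_beta(Y)
    fit = deconvolve(beta, K=2, n_iter=10, n_restarts=1, seed=0)
    perm = np.array([5, 0, 3, 1, 4, 2])
    beta_p = BetaMatrix(Y[:, perm], beta.cpg_ids, [beta.specimen_ids[i] for i in perm])
    fit_p = deconvolve(beta_p, K=2, n_iter=10, n_restarts=1, seed=0)
    np.testing.assert_allclose(fit_p.M.values, fit.M.values, atol=1e-9)
    np.testing.assert_allclose(fit_p.Omega.values, fit.Omega.values[perm], atol=1e-9)


def test_k_exceeding_n_rejected(small_truth):
    with pytest.raises(ValueError):
        deconvolve(small_truth.Y, K=small_truth.Y.shape[1] + 1)


# --- reference projection ---------------------------------------------------

def test_self_projection_is_identity_pattern():
    rng = np.random.default_rng(6)
    R = rng.uniform(0, 1, (100, 3))
    ref = MethylomeMatrix(R, [f"cg{j}" for j in range(100)], ["t1", "t2", "t3"])
    beta = BetaMatrix(R.copy(), list(ref.cpg_ids), ["a", "b", "c"])
    omega = project_to_reference(beta, ref)
    np.testing.assert_allclose(omega.values, np.eye(3), atol=1e-7)


def test_projection_recovers_interior_proportions():
    rng = np.random.default_rng(7)
    M0 = rng.uniform(0, 1, (200, 3))
    W0 = rng.dirichlet((2, 3, 4), size=15)
    ref = MethylomeMatrix(M0, [f"cg{j}" for j in range(200)], ["t1", "t2", "t3"])
    beta = make_beta(M0 @ W0.T)
    omega = project_to_reference(beta, ref)
    np.testing.assert_allclose(omega.values, W0, atol=1e-6)


def test_projection_k1_closed_form():
    rng = np.random.default_rng(8)
    c = rng.uniform(0.1, 0.9, 50)
    y = rng.uniform(0, 1, 50)
    ref = MethylomeMatrix(c[:, None], [f"cg{j}" for j in range(50)], ["t1"])
    beta = make_beta(y[:, None])
    w = project_to_reference(beta, ref).values[0, 0]
    expect = np.clip((y @ c) / (c @ c), 0.0, 1.0)
    assert abs(w - expect) < 1e-8


def test_projection_empty_intersection_errors():
    ref = MethylomeMatrix(np.full((5, 1), 0.5), [f"x{j}" for j in range(5)], ["t"])
    beta = make_beta(np.full((5, 2), 0.5))
    with pytest.raises(ValueError):
        project_to_reference(beta, ref)


def test_residualize_self_gives_identity_and_zero_residual():
    rng = np.random.default_rng(9)
    M0 = MethylomeMatrix(rng.uniform(0, 1, (80, 3)), [f"cg{j}" for j in range(80)],
                         ["t1", "t2", "t3"])
    Psi, resid = residualize_against_reference(M0, M0)
    np.testing.assert_allclose(Psi.values, np.eye(3), atol=1e-6)
    assert np.abs(resid).max() < 1e-6


def test_residualize_convex_combination_vanishes():
    rng = np.random.default_rng(10)
    base = rng.uniform(0, 1, (80, 3))
    mix = rng.dirichlet((1, 1, 1), size=2).T  # 3 x 2 column-stochastic
    ids = [f"cg{j}" for j in range(80)]
    M0 = MethylomeMatrix(base, ids, ["t1", "t2", "t3"])
    M1 = MethylomeMatrix(base @ mix, ids, ["f1", "f2"])
    Psi, resid = residualize_against_reference(M1, M0)
    assert np.abs(resid).max() < 1e-6
    np.testing.assert_allclose(Psi.values, mix, atol=1e-5)


def test_residualize_orthogonal_support_recovers_weights():
    # reference columns live on disjoint CpG blocks
    M0v = np.zeros((60, 2))
    M0v[:30, 0] = 0.9
    M0v[30:, 1] = 0.8
    ids = [f"cg{j}" for j in range(60)]
    M0 = MethylomeMatrix(M0v, ids, ["t1", "t2"])
    w = np.array([0.3, 0.6])
    M1 = MethylomeMatrix((M0v * w[None, :]).sum(axis=1, keepdims=True), ids, ["f1"])
    Psi, resid = residualize_against_reference(M1, M0)
    np.testing.assert_allclose(Psi.values[:, 0], w, atol=1e-7)
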