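"""Profile-likelihood estimator: linear-algebra oracles and invariants."""

import numpy as np
import pytest

from tgvis import SimConfig, fit_cis_effects, fit_tgvis, simulate_locus
from tgvis.estimator import (LocusEig, TGVISConfig, bic, profile_likelihood,
                             score_test, stacked_inputs, update_sigma_alpha,
                             update_sigma_upsilon, update_upsilon)


def random_corr(rng, m, extra=3):
    A = rng.standard_normal((m, m + extra))
    R = np.corrcoef(A)
    return 0.95 * R + 0.05 * np.eye(m)


# ---------------------------------------------------------------- stacking
def test_stacked_inputs_basis_reduction(rng):
    M = 6
    R = random_corr(rng, M)
    ahat = rng.standard_normal(M) * 3
    B = np.zeros((M, 1))
    B[0, 0] = 1.0   # pair predictor == variant 0
    z, corr, w = stacked_inputs(ahat, B, R)
    assert z[0] == pytest.approx(ahat[0] / np.sqrt(R[0, 0]))
    np.testing.assert_allclose(corr[0, 1:], R[0] / np.sqrt(R[0, 0]), atol=1e-12)


def test_stacked_inputs_duplicate_columns_fully_correlated(rng):
    M = 8
    R = random_corr(rng, M)
    b = rng.standard_normal(M) * (rng.random(M) < 0.4)
    b[0] = 1.0
    B = np.column_stack([b, b])
    _, corr, _ = stacked_inputs(rng.standard_normal(M), B, R)
    assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_stacked_inputs_matches_predictor_covariance_oracle(rng):
    """The stacked correlation equals the correlation of the linear
    predictors computed through the LD square root (independent route)."""
    M, K = 4, 2
    R = random_corr(rng, M)
    B = rng.standard_normal((M, K))
    ahat = rng.standard_normal(M)
    z, corr, w = stacked_inputs(ahat, B, R)
    w_half, V = np.linalg.eigh(R)
    Rhalf = V @ np.diag(np.sqrt(w_half)) @ V.T
    preds = np.column_stack([Rhalf @ B, Rhalf])   # pair scores then variants
    oracle = (preds.T @ preds) / np.outer(np.linalg.norm(preds, axis=0),
                                          np.linalg.norm(preds, axis=0))
    np.testing.assert_allclose(corr, oracle, atol=1e-10)


# ------------------------------------------------------------- PQL / REML
def test_update_upsilon_zero_residual(rng):
    M = 5
    R = random_corr(rng, M)
    eig = LocusEig(R)
    ahat = rng.standard_normal(M)
    ups = update_upsilon(ahat, ahat, eig, 1.0, 0.5)
    np.testing.assert_allclose(ups, 0.0, atol=1e-12)


def test_update_upsilon_identity_scalar_case():
    M = 4
    eig = LocusEig(np.eye(M))
    ahat = np.array([1.0, -2.0, 0.5, 3.0])
    ups = update_upsilon(ahat, np.zeros(M), eig, 1.0, 1.0)
    np.testing.assert_allclose(ups, ahat / 2.0, atol=1e-12)


def test_update_upsilon_matches_dense_inverse():
    R = np.full((3, 3), 0.4) + 0.6 * np.eye(3)
    eig = LocusEig(R)
    resid = np.array([1.0, 2.0, -1.0])
    lam = 1.0 / 0.3
    expect = np.linalg.inv(R + lam * np.eye(3)) @ resid
    got = update_upsilon(resid, np.zeros(3), eig, 1.0, 0.3)
    np.testing.assert_allclose(got, expect, atol=1e-10)


def test_update_upsilon_ridge_limit_monotone():
    """As sigma_upsilon^2 -> 0 the BLUPs shrink to zero, monotonically for
    identity LD."""
    M = 6
    eig = LocusEig(np.eye(M))
    resid = np.linspace(-2, 2, M)
    prev = None
    for sv2 in (1.0, 0.1, 0.01, 1e-4):
        u = np.abs(update_upsilon(resid, np.zeros(M), eig, 1.0, sv2))
        if prev is not None:
            assert np.all(u <= prev + 1e-15)
        prev = u
    np.testing.assert_allclose(prev, 0.0, atol=1e-3)


def test_update_sigma_upsilon_trace_identities(rng):
    M = 4
    eig_I = LocusEig(np.eye(M))
    # upsilon = 0, lambda = 1: tr((R+I)^-1)/M = 1/2
    assert update_sigma_upsilon(np.zeros(M), eig_I, 1.0, 1.0, M) == \
        pytest.approx(0.5)
    # lambda -> infinity: the update vanishes
    assert update_sigma_upsilon(np.zeros(M), eig_I, 1.0, 1e-12, M) == \
        pytest.approx(0.0, abs=1e-9)
    R = random_corr(rng, M)
    eig = LocusEig(R)
    ups = rng.standard_normal(M)
    lam = 1.0 / 0.7
    expect = (ups @ ups) / M + np.trace(
        np.linalg.inv(R + lam * np.eye(M))) / M
    got = update_sigma_upsilon(ups, eig, 1.0, 0.7, M)
    assert got == pytest.approx(expect, abs=1e-10)


def test_update_sigma_alpha_quadratic_form(rng):
    M = 5
    R = random_corr(rng, M)
    eig = LocusEig(R)
    B = rng.standard_normal((M, 2))
    theta = rng.standard_normal(2)
    gamma = rng.standard_normal(M) * 0.1
    ups = rng.standard_normal(M) * 0.1
    mean = R @ (B @ theta + gamma + ups)
    # perfect fit
    assert update_sigma_alpha(mean, B, theta, gamma, ups, eig, R) == \
        pytest.approx(0.0, abs=1e-12)
    ahat = mean + rng.standard_normal(M)
    resid = ahat - mean
    expect = resid @ np.linalg.solve(R, resid) / M
    got = update_sigma_alpha(ahat, B, theta, gamma, ups, eig, R)
    assert got == pytest.approx(expect, abs=1e-9)
    # identity LD: plain mean squared residual
    eye = LocusEig(np.eye(M))
    got_i = update_sigma_alpha(resid, np.zeros((M, 0)), np.zeros(0),
                               np.zeros(M), np.zeros(M), eye, np.eye(M))
    assert got_i == pytest.approx(float(resid @ resid) / M)


# ---------------------------------------------------------------- BIC
def test_bic_arithmetic_and_monotonicity():
    assert bic(1.0, 400, 0) == 0.0
    assert bic(1.0, 400, 4) == pytest.approx(4 * np.log(400) / 400)
    assert bic(1.0, 400, 4) == pytest.approx(0.0599, abs=2e-4)
    assert bic(0.5, 100, 3) < bic(0.5, 100, 5)


# ------------------------------------------------------------ score test
def test_score_test_perfect_fit_accepts():
    M = 6
    R = np.eye(M)
    eig = LocusEig(R)
    A = np.eye(M)[:, :2]
    vt = np.array([3.0, -2.0])
    st = score_test(A @ vt, A, vt, R, eig)
    assert st.u == pytest.approx(0.0, abs=1e-20)
    assert st.p_value == pytest.approx(1.0)


def test_score_test_trace_arithmetic_identity_ld():
    M = 12
    R = np.eye(M)
    eig = LocusEig(R)
    st = score_test(np.zeros(M), np.zeros((M, 0)), np.zeros(0), R, eig)
    assert st.e == pytest.approx(M / 2)
    assert st.h == pytest.approx(M / 2)
    assert st.kappa == pytest.approx(0.5)
    assert st.dof == pytest.approx(M)


def test_score_test_satterthwaite_moment_identities(rng):
    """kappa * dof == e and 2 * kappa^2 * dof == h hold algebraically."""
    M = 9
    R = random_corr(rng, M)
    eig = LocusEig(R)
    A = np.column_stack([R @ rng.standard_normal(M), R[:, 3]])
    st = score_test(rng.standard_normal(M), A, rng.standard_normal(2), R, eig)
    assert st.kappa * st.dof == pytest.approx(st.e, rel=1e-10)
    assert 2 * st.kappa ** 2 * st.dof == pytest.approx(st.h, rel=1e-10)


def test_score_test_traces_match_dense_projection_oracle(rng):
    M = 8
    R = random_corr(rng, M)
    eig = LocusEig(R)
    A = np.column_stack([R @ rng.standard_normal(M), R[:, 2], R[:, 5]])
    st = score_test(rng.standard_normal(M), A, rng.standard_normal(3), R, eig)
    Ri = np.linalg.inv(R)
    P = Ri - Ri @ A @ np.linalg.inv(A.T @ Ri @ A) @ A.T @ Ri
    PR2 = P @ R @ R
    assert st.e == pytest.approx(0.5 * np.trace(PR2), rel=1e-8)
    assert st.h == pytest.approx(0.5 * np.trace(PR2 @ PR2), rel=1e-8)


def test_score_test_drops_collinear_columns(rng):
    M = 6
    R = random_corr(rng, M)
    eig = LocusEig(R)
    col = R @ rng.standard_normal(M)
    A = np.column_stack([col, col])
    with pytest.warns(RuntimeWarning):
        st = score_test(rng.standard_normal(M), A, np.array([1.0, 1.0]),
                        R, eig)
    assert np.isfinite(st.p_value)


def test_score_test_null_calibration(rng):
    """Empirical rejection rate of the Satterthwaite chi-square mixture at
    level 0.05 under the null, A empty, over 1000 draws of a ~ N(0, R)."""
    M = 400
    from tgvis.simulator import build_ld
    R = build_ld(M)
    eig = LocusEig(R)
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(M))
    local = np.random.default_rng(77)
    empty = np.zeros((M, 0))
    rej = 0
    n_rep = 1000
    for _ in range(n_rep):
        ahat = chol @ local.standard_normal(M)
        st = score_test(ahat, empty, np.zeros(0), R, eig)
        rej += st.p_value < 0.05
    assert 0.03 <= rej / n_rep <= 0.08


# ----------------------------------------------------- profile likelihood
@pytest.fixture(scope="module")
def fitted_small_locus():
    cfg = SimConfig(n_genes=4, n_tissues=2, M=60, block_size=20,
                    causal_pairs=(0, 7), shared_pool_size=10,
                    scenario="none", seed=11)
    locus, truth = simulate_locus(cfg)
    config = TGVISConfig(l_grid=(2, 3, 4))
    B = fit_cis_effects(locus)
    return locus, truth, config, B


def test_fit_is_deterministic(fitted_small_locus):
    locus, truth, config, B = fitted_small_locus
    f1 = fit_tgvis(locus, config, B=B)
    f2 = fit_tgvis(locus, config, B=B)
    np.testing.assert_array_equal(f1.theta, f2.theta)
    np.testing.assert_array_equal(f1.gamma, f2.gamma)
    np.testing.assert_array_equal(f1.upsilon, f2.upsilon)
    assert f1.L_selected == f2.L_selected


def test_fit_invariants(fitted_small_locus):
    locus, truth, config, B = fitted_small_locus
    fit = fit_tgvis(locus, config, B=B)
    # score-test acceptance forces the infinitesimal component to zero
    if not fit.infinitesimal_active:
        assert not fit.upsilon.any()
        assert fit.sigma_upsilon2 == 0.0
    # theta/gamma nonzeros are exactly the selected stacked coordinates
    members = set()
    for cs in fit.credible_sets:
        members.update(fit.stacked_index(m) for m in cs.members)
    P = locus.n_pairs
    assert set(np.flatnonzero(fit.theta)) <= {g for g in members if g < P}
    assert set(np.flatnonzero(fit.gamma) + P) <= {g for g in members
                                                  if g >= P}
    assert len(fit.bic_trace) == len(config.l_grid)


def test_causal_pair_recovered(fitted_small_locus):
    locus, truth, config, B = fitted_small_locus
    fit = fit_tgvis(locus, config, B=B)
    called = fit.called_pairs()
    assert called & set(np.flatnonzero(truth.theta))
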