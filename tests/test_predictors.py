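import numpy as np
import pytest

import genovar as gv
from genovar.basepop import base_design, make_B
from genovar.io import DataError
from genovar.predictors import best_predictor, ld_contribution, unconditional_expectation

from conftest import make_dataset


def test_V_marker_form_equals_equivalent_form():
    """sigma_b^2 tr(SigmaHat_X) = sigma_g^2 tr(G)/(n-1), both code paths."""
    ds = make_dataset(n=40, p=60, seed=51)
    b = gv.build_grm(ds.genotypes)
    fit = gv.fit_gblup(ds.phenotypes, b)
    V = gv.estimate(fit, b, "V")
    marker_form = fit.vc.sigma_b2 * gv.marker_covariance(b.centered).trace()
    assert V.value == pytest.approx(marker_form, abs=1e-10 * max(1, V.value))


def test_Vs_star_is_fitted_sigma_g2(rem_fit):
    _, b, fit = rem_fit
    assert gv.estimate(fit, b, "V_s_star").value == fit.vc.sigma_g2


def test_known_effects_limit_recovers_realized_variance():
    """With Sigma_{beta|y} = 0 and mu_beta = beta, BP collapses to s_g^2."""
    ds = make_dataset(n=50, p=20, seed=53)
    b = gv.build_grm(ds.genotypes)
    cov = gv.marker_covariance(b.centered)
    beta = ds.true_beta[: b.p]  # no markers dropped at these MAFs
    assert cov.quadratic_form(beta) == pytest.approx(ds.realized_sg2, rel=1e-12)


def test_decomposition_W_equals_V_plus_L(rem_fit):
    ds, b, fit = rem_fit
    V, W = gv.estimate(fit, b, "V"), gv.estimate(fit, b, "W")
    assert W.ld_component == pytest.approx(W.value - V.value, abs=1e-15)
    ld = ld_contribution(fit, b)
    assert ld.value == pytest.approx(W.value - V.value, abs=1e-12)


def test_explicit_ld_sum_matches_identity(small_fit):
    """The printed double sum over SigmaHat_X equals W - V; the naive
    double loop agrees with the vectorized evaluation."""
    ds, b, fit = small_fit
    W = gv.estimate(fit, b, "W")
    V = gv.estimate(fit, b, "V")
    ld = ld_contribution(fit, b, explicit=True, breakdown=True)
    assert ld.value == pytest.approx(W.value - V.value, abs=1e-9)
    assert ld.value == pytest.approx(ld.diagonal + ld.off_diagonal, abs=1e-12)
    # brute-force double loop oracle
    mb = gv.marker_blups(fit, b)
    weights = np.outer(mb.mu_beta, mb.mu_beta) - mb.cov_mu_beta
    S = gv.marker_covariance(b.centered).matrix
    diag = sum(weights[j, j] * S[j, j] for j in range(b.p))
    off = sum(weights[i, j] * S[i, j]
              for i in range(b.p) for j in range(b.p) if i != j)
    assert ld.diagonal == pytest.approx(diag, abs=1e-12)
    assert ld.off_diagonal == pytest.approx(off, abs=1e-12)


def test_diagonal_weights_give_zero_offdiagonal():
    """If SigmaHat_X is diagonal, the off-diagonal partial sum vanishes."""
    # independent markers on disjoint samples cannot be built exactly, so
    # check the algebra directly on a synthetic diagonal SigmaHat
    rng = np.random.default_rng(9)
    weights = np.diag(rng.normal(size=5) ** 2)
    S = np.diag(rng.uniform(1, 2, size=5))
    prod = weights * S
    assert float(prod.sum()) - float(np.trace(prod)) == 0.0


def test_base_population_dual_path():
    """W* via B = R^-.5 P R^-.5 equals the marker form with SigmaHat_X*."""
    R = gv.make_relationship("block_family", 30, block_size=5, relatedness=0.4)
    ds = make_dataset(n=30, p=12, seed=57, relationship=R)
    b = gv.build_grm(ds.genotypes)
    fit = gv.fit_gblup(ds.phenotypes, b)
    B = make_B("base", R=R)
    Wst = best_predictor(fit, B, b)
    Vst = unconditional_expectation(fit, B, b)
    mb = gv.marker_blups(fit, b)
    C = base_design(b, R)
    Sstar = C.T @ C / (b.n - 1)
    M = np.outer(mb.mu_beta, mb.mu_beta) + mb.cov_beta_given_y
    w_marker = float(np.sum(Sstar * M))
    v_marker = fit.vc.sigma_b2 * float(np.trace(Sstar))
    assert Wst.value == pytest.approx(w_marker, abs=1e-9 * max(1, abs(w_marker)))
    assert Vst.value == pytest.approx(v_marker, abs=1e-9 * max(1, abs(v_marker)))
    assert Wst.ld_component == pytest.approx(Wst.value - Vst.value, abs=1e-12)


def test_w_family_nonnegative(rem_fit):
    _, b, fit = rem_fit
    R = gv.make_relationship("block_family", b.n, block_size=6, relatedness=0.3)
    for est, kw in [("W", {}), ("W_star", {"R": R}), ("W_s_star", {})]:
        assert gv.estimate(fit, b, est, **kw).value >= 0


def test_allele_flip_invariance():
    ds = make_dataset(n=60, p=40, seed=59)
    flipped = ds.genotypes.values.copy()
    flipped[:, 1::2] = 2.0 - flipped[:, 1::2]
    gf = gv.GenotypeMatrix(flipped, ds.genotypes.sample_ids, ds.genotypes.marker_ids)
    b1, b2 = gv.build_grm(ds.genotypes), gv.build_grm(gf)
    f1 = gv.fit_gblup(ds.phenotypes, b1)
    f2 = gv.fit_gblup(ds.phenotypes, b2)
    for est in ("V", "W"):
        # small drift allowed: the flip perturbs G at floating-point level,
        # which moves the REML optimum by O(eps) on the lambda scale
        assert gv.estimate(f1, b1, est).value == pytest.approx(
            gv.estimate(f2, b2, est).value, rel=1e-6)


def test_heritability_summary(rem_fit):
    ds, b, fit = rem_fit
    V, W = gv.estimate(fit, b, "V"), gv.estimate(fit, b, "W")
    h2 = gv.heritability_summary(fit, V, W, ds.phenotypes)
    s2y = np.var(ds.phenotypes.values, ddof=1)
    assert h2.phenotypic_variance == pytest.approx(s2y)
    assert h2.h2_tilde_W == pytest.approx(W.value / (W.value + fit.vc.sigma_e2))
    assert 0 <= h2.h2_tilde_V <= 1 and 0 <= h2.h2_tilde_W <= 1


def test_heritability_on_scaled_phenotype_equals_W():
    """With var(y) scaled to 1, h2_W is numerically W itself."""
    ds = make_dataset(n=80, p=50, seed=61)
    y = ds.phenotypes.scaled()
    b = gv.build_grm(ds.genotypes)
    fit = gv.fit_gblup(y, b)
    V, W = gv.estimate(fit, b, "V"), gv.estimate(fit, b, "W")
    h2 = gv.heritability_summary(fit, V, W, y)
    assert h2.h2_W == W.value / h2.phenotypic_variance
    assert h2.h2_W == pytest.approx(W.value, rel=1e-12)


def test_heritability_rejects_base_population(rem_fit):
    _, b, fit = rem_fit
    Vss = gv.estimate(fit, b, "V_s_star")
    W = gv.estimate(fit, b, "W")
    with pytest.raises(DataError, match="current population"):
        gv.heritability_summary(fit, Vss, W, np.zeros(b.n))
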