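"""Replicated simulation studies of the variance predictors.

These are the package's standing numerical experiments: REML parameter
recovery, unbiasedness and MSE-dominance of the best predictor against the
realized random target, the Bayesian-equivalence check of M2 vs W, and the
phenotypic-variance decomposition W + sigma_e^2 = var(y). Each study
generates its data under the random-effects model the estimators assume,
holds the genotype matrix fixed across replicates (so the one-time
eigendecomposition of G is amortized), and returns plain dictionaries of
summary numbers together with Monte-Carlo standard errors.
"""

from __future__ import annotations

import numpy as np

from genovar.brr import BrrConfig, m2, run_brr
from genovar.grm import build_grm, marker_covariance
from genovar.predictors import estimate
from genovar.reml import EigenGRM, fit_gblup
from genovar.simulate import simulate_genotypes, simulate_phenotypes


def _fixed_x_setup(n: int, p: int, seed: int, sigma_g2: float):
    """One genotype draw plus everything reusable across phenotype replicates."""
    X = simulate_genotypes(n, p, seed=seed)
    bundle = build_grm(X)
    eig = EigenGRM(bundle.G)
    sigma_b2 = sigma_g2 / bundle.c
    return X, bundle, eig, sigma_b2


def recovery_study(
    n: int = 500,
    p: int = 1000,
    reps: int = 200,
    sigma_g2: float = 0.5,
    sigma_e2: float = 0.5,
    seed: int = 0,
) -> dict:
    """REML parameter recovery at fixed X over replicated (beta, eps) draws.

    Returns the Monte-Carlo means of sigma_g2-hat and sigma_e2-hat with
    their standard errors; under the correctly specified model both should
    sit within a few SE of the generating values.
    """
    X, bundle, eig, sigma_b2 = _fixed_x_setup(n, p, seed, sigma_g2)
    g2, e2 = np.empty(reps), np.empty(reps)
    for r in range(reps):
        ds = simulate_phenotypes(X, sigma_b2, sigma_e2, mu=1.0, seed=seed + 1 + r)
        fit = fit_gblup(ds.phenotypes, eig, scaling_c=bundle.c)
        g2[r], e2[r] = fit.vc.sigma_g2, fit.vc.sigma_e2
    return {
        "sigma_g2_true": sigma_g2, "sigma_e2_true": sigma_e2,
        "mean_sigma_g2": float(g2.mean()), "se_sigma_g2": float(g2.std(ddof=1) / np.sqrt(reps)),
        "mean_sigma_e2": float(e2.mean()), "se_sigma_e2": float(e2.std(ddof=1) / np.sqrt(reps)),
        "reps": reps, "n": n, "p": p,
    }


def bp_optimality_study(
    n: int = 300,
    p: int = 50,
    reps: int = 500,
    sigma_g2: float = 0.5,
    sigma_e2: float = 0.5,
    seed: int = 0,
) -> dict:
    """W vs V against the realized random target s_g^2 at fixed X.

    The best predictor is unbiased for the random s_g^2 and minimizes the
    mean squared prediction error, so across replicates mean(W - s_g^2)
    should be ~0 and MSE(W) <= MSE(V).
    """
    X, bundle, eig, sigma_b2 = _fixed_x_setup(n, p, seed, sigma_g2)
    W = np.empty(reps)
    V = np.empty(reps)
    target = np.empty(reps)
    for r in range(reps):
        ds = simulate_phenotypes(X, sigma_b2, sigma_e2, mu=1.0, seed=seed + 1 + r)
        fit = fit_gblup(ds.phenotypes, eig, scaling_c=bundle.c)
        W[r] = estimate(fit, bundle, "W").value
        V[r] = estimate(fit, bundle, "V").value
        target[r] = ds.realized_sg2
    bias = W - target
    return {
        "mean_bias_W": float(bias.mean()),
        "se_bias_W": float(bias.std(ddof=1) / np.sqrt(reps)),
        "mse_W": float(np.mean((W - target) ** 2)),
        "mse_V": float(np.mean((V - target) ** 2)),
        "reps": reps, "n": n, "p": p,
    }


def bayes_equivalence_study(
    n: int = 50,
    p: int = 8,
    draws: int = 10_000,
    seed: int = 0,
) -> dict:
    """M2 with variance components fixed at REML vs the closed-form W.

    With sigma_b^2 and sigma_e^2 pinned, the BRR posterior is the exact
    conditional normal of the gBLUP model, so the Monte-Carlo posterior
    mean of beta' SigmaHat_X beta converges to W.
    """
    X = simulate_genotypes(n, p, seed=seed)
    bundle = build_grm(X)
    sigma_b2 = 0.5 / marker_covariance(bundle.centered).trace()
    ds = simulate_phenotypes(X, sigma_b2, 0.5, mu=1.0, seed=seed + 1)
    fit = fit_gblup(ds.phenotypes, bundle)
    W = estimate(fit, bundle, "W").value
    cfg = BrrConfig(chain=draws + 2_000, burnin=2_000, thin=1, seed=seed,
                    fix_vc=(fit.vc.sigma_b2, fit.vc.sigma_e2))
    post = run_brr(ds.phenotypes, bundle, cfg)
    res = m2(post, marker_covariance(bundle.centered))
    return {"m2": res.value, "mc_se": res.mc_se, "W": W,
            "abs_diff": abs(res.value - W), "draws": res.n_draws, "n": n, "p": p}


def decomposition_study(
    n: int = 200,
    p: int = 300,
    reps: int = 100,
    seed: int = 0,
) -> dict:
    """Phenotypic-variance decomposition on scaled phenotypes.

    After scaling var(y) to 1, the best predictor satisfies
    W + sigma_e^2 = var(y) almost exactly (the orthogonal-projection
    property of the conditional expectation at the REML optimum); the study
    reports the worst relative deviation across replicates.
    """
    rel_err = np.empty(reps)
    for r in range(reps):
        X = simulate_genotypes(n, p, seed=seed + 1000 * r)
        bundle = build_grm(X)
        sigma_b2 = 0.5 / marker_covariance(bundle.centered).trace()
        ds = simulate_phenotypes(X, sigma_b2, 0.5, mu=1.0, seed=seed + 1000 * r + 1)
        y = ds.phenotypes.scaled()
        fit = fit_gblup(y, bundle)
        W = estimate(fit, bundle, "W", ).value
        s2y = float(np.var(y.values, ddof=1))
        rel_err[r] = abs(W + fit.vc.sigma_e2 - s2y) / s2y
    return {"max_rel_err": float(rel_err.max()), "mean_rel_err": float(rel_err.mean()),
            "reps": reps, "n": n, "p": p}
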