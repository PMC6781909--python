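"""Bayesian ridge regression Gibbs sampler and the M2 variance estimator.

The model is the Bayesian reading of the marker model: y = mu*1 + Z beta +
eps with Z the centered genotypes, beta_j ~ N(0, sigma_b^2) i.i.d., and
scaled-inverse-chi-square priors on the two variance components (flat prior
on mu). The posterior mean of the additive genomic variance,

    M2 = (1/M) sum_m beta^(m)' SigmaHat_X beta^(m),

is the Bayesian analogue of the closed-form best predictor W; with the
variance components *fixed* at their REML estimates the two coincide in
expectation, which is the cross-check the test-suite runs.

Each quadratic form is evaluated implicitly as ||Z beta||^2/(n-1), so the
sampler never forms a p x p matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from genovar.grm import GrmBundle, MarkerCovariance
from genovar.io import DataError, PhenotypeVector


@dataclass
class BrrConfig:
    chain: int = 12_000
    burnin: int = 2_000
    thin: int = 10
    seed: int = 0
    prior_df: float = 5.0
    # prior scales; None -> matched to a 50/50 split of var(y) at run time
    prior_scale_b: float | None = None
    prior_scale_e: float | None = None
    fix_vc: tuple[float, float] | None = None   # (sigma_b2, sigma_e2)

    def __post_init__(self) -> None:
        if self.chain <= self.burnin:
            raise DataError("chain length must exceed burn-in")
        if (self.chain - self.burnin) % self.thin != 0:
            raise DataError("(chain - burnin) must be a multiple of thin")


@dataclass
class BrrPosterior:
    beta_samples: np.ndarray            # M x p retained draws
    vc_samples: np.ndarray | None       # M x 2 (sigma_b2, sigma_e2), None if fixed
    mu_samples: np.ndarray
    config: BrrConfig
    fixed_vc: bool

    @property
    def n_draws(self) -> int:
        return self.beta_samples.shape[0]


def run_brr(y: PhenotypeVector | np.ndarray, bundle: GrmBundle, config: BrrConfig) -> BrrPosterior:
    """Gibbs sampler for Bayesian ridge regression on centered genotypes.

    Single-site sweep over marker effects with running-residual updates;
    scaled-inverse-chi-square full conditionals for the variance components
    unless ``config.fix_vc`` pins them. Fully reproducible from the seed.
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    Z = bundle.centered
    n, p = Z.shape
    if yv.size != n:
        raise DataError("phenotype length does not match genotypes")
    rng = np.random.default_rng(config.seed)
    zsq = np.einsum("ij,ij->j", Z, Z)
    vary = float(np.var(yv, ddof=1))
    df0 = config.prior_df
    # prior means target a 50/50 split of the phenotypic variance
    s0b = config.prior_scale_b
    if s0b is None:
        tr_sigma = float(zsq.sum()) / (n - 1)
        s0b = 0.5 * vary / tr_sigma * (df0 - 2.0) / df0 if df0 > 2 else 0.5 * vary / tr_sigma
    s0e = config.prior_scale_e
    if s0e is None:
        s0e = 0.5 * vary * (df0 - 2.0) / df0 if df0 > 2 else 0.5 * vary

    fixed = config.fix_vc is not None
    if fixed:
        s2b, s2e = map(float, config.fix_vc)
    else:
        s2b, s2e = s0b, s0e

    beta = np.zeros(p)
    mu = float(yv.mean())
    resid = yv - mu            # y - mu - Z beta with beta = 0
    keep = (config.chain - config.burnin) // config.thin
    beta_out = np.empty((keep, p))
    vc_out = None if fixed else np.empty((keep, 2))
    mu_out = np.empty(keep)
    k = 0
    for it in range(config.chain):
        # intercept
        mu_new = rng.normal(float(resid.mean()) + mu, np.sqrt(s2e / n))
        resid += mu - mu_new
        mu = mu_new
        # marker effects, single-site
        ratio = s2e / s2b
        for j in range(p):
            zj = Z[:, j]
            rj = resid + zj * beta[j]          # residual with marker j removed
            prec = zsq[j] + ratio
            mean_j = float(zj @ rj) / prec
            bj = rng.normal(mean_j, np.sqrt(s2e / prec))
            resid = rj - zj * bj
            beta[j] = bj
        if not np.isfinite(beta).all():
            raise RuntimeError(f"divergent chain at iteration {it}")
        if not fixed:
            s2b = (df0 * s0b + float(beta @ beta)) / rng.chisquare(df0 + p)
            s2e = (df0 * s0e + float(resid @ resid)) / rng.chisquare(df0 + n)
        if it >= config.burnin and (it - config.burnin) % config.thin == 0:
            beta_out[k] = beta
            mu_out[k] = mu
            if not fixed:
                vc_out[k] = (s2b, s2e)
            k += 1
    return BrrPosterior(beta_out, vc_out, mu_out, config, fixed)


@dataclass
class M2Estimate:
    value: float
    mc_se: float
    n_draws: int
    population: Literal["current", "base"]


def m2(posterior: BrrPosterior, cov: MarkerCovariance) -> M2Estimate:
    """Monte-Carlo posterior mean of the quadratic form beta' SigmaHat beta.

    ``cov.population`` selects M2 (current, SigmaHat_X) vs M2* (base,
    SigmaHat_{X*}). The Monte-Carlo standard error is estimated by batch
    means to absorb chain autocorrelation.
    """
    if posterior.n_draws == 0:
        raise DataError("empty posterior")
    if cov.centered is not None:
        # implicit: q_m = ||C beta_m||^2 / (n-1), vectorized over draws
        V = posterior.beta_samples @ cov.centered.T
        q = np.einsum("ij,ij->i", V, V) / (cov.n - 1)
    else:
        B = posterior.beta_samples
        q = np.einsum("ij,jk,ik->i", B, cov.matrix, B)
    M = q.size
    nb = min(50, M)
    usable = (M // nb) * nb
    batches = q[:usable].reshape(nb, -1).mean(axis=1)
    se = float(batches.std(ddof=1) / np.sqrt(nb)) if nb > 1 else float("nan")
    return M2Estimate(float(q.mean()), se, M, cov.population)
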