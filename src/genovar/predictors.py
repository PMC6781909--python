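"""Estimators and predictors of the random additive genomic variance.

Two families, both plug-in estimates from one REML fit:

* Unconditional expectations (the GCTA-GREML viewpoint):
    V    = sigma_b^2 tr(SigmaHat_X)        = sigma_g^2 tr(G) / (n-1)
    V*   = sigma_b^2 tr(SigmaHat_X*)       = sigma_g^2 tr(P R^-.5 G R^-.5)/(n-1)
    Vs*  = sigma_g^2                        (GRM used as R; simplified form)
  Only the diagonal of the marker covariance enters: LD is ignored.

* Best predictors (conditional expectations given y):
    BP(s^2_{g,B}) = tr(B [mu_{g|y} mu_{g|y}' + Sigma_{g|y}]) / (n-1)
  with W (B = I), W* (B = R^-.5 P R^-.5) and Ws* (GRM-based B). The
  difference L(y) = W - V is exactly the LD contribution: a double sum of
  the elements of SigmaHat_X weighted by mu_{beta|y} mu_{beta|y}' -
  Cov(mu_{beta|y}).

The n-dimensional (equivalent-model) forms are the default computational
path at any p; the marker-form expressions are kept as cross-checks below a
size cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from genovar.basepop import BMatrix, base_design, make_B
from genovar.grm import DEFAULT_P_CAP, GrmBundle, MarkerCovariance, marker_covariance
from genovar.io import DataError, PhenotypeVector, RelationshipMatrix
from genovar.reml import GblupFit, MarkerBlups, marker_blups

Estimator = Literal["V", "V_star", "V_s_star", "W", "W_star", "W_s_star"]

#: p at or below which best_predictor also evaluates the marker-form
#: expression and asserts agreement with the equivalent-model form
VERIFY_P_CAP = 2000


@dataclass
class VariancePrediction:
    estimator: Estimator
    population: Literal["current", "base"]
    value: float
    ld_component: float | None = None      # W-family only: L(y) = W - V
    b_source: str = "none"
    n: int = 0


@dataclass
class HeritabilitySummary:
    h2_V: float
    h2_W: float
    h2_tilde_V: float
    h2_tilde_W: float
    phenotypic_variance: float


def _require_converged(fit: GblupFit) -> None:
    if not fit.vc.converged:
        raise RuntimeError("REML fit did not converge")


def unconditional_expectation(fit: GblupFit, B: BMatrix, bundle: GrmBundle) -> VariancePrediction:
    """E[s^2_{g,B}] = sigma_g^2 tr(B G) / (n - 1).

    For the identity B this is V = sigma_b^2 tr(SigmaHat_X); both forms are
    algebraically identical and the marker form is exercised in the tests.
    """
    _require_converged(fit)
    n = bundle.n
    if B.is_identity:
        value = fit.vc.sigma_g2 * float(np.trace(bundle.G)) / (n - 1)
        return VariancePrediction("V", "current", value, None, "none", n)
    value = fit.vc.sigma_g2 * float(np.sum(B.matrix * bundle.G)) / (n - 1)
    name: Estimator = "V_s_star" if B.transform_source == "grm" else "V_star"
    return VariancePrediction(name, "base", value, None, B.transform_source, n)


def best_predictor(
    fit: GblupFit,
    B: BMatrix,
    bundle: GrmBundle,
    verify_cap: int = VERIFY_P_CAP,
) -> VariancePrediction:
    """BP(s^2_{g,B}) = tr(B [mu_{g|y} mu_{g|y}' + Sigma_{g|y}]) / (n - 1).

    Computed in the n-dimensional equivalent-model representation. For
    p <= ``verify_cap`` the marker-form expression
    tr(SigmaHat [mu_beta mu_beta' + Sigma_{beta|y}]) is evaluated as well
    and must agree to within 1e-9 of scale, guarding against convention
    drift between the two parameterizations.
    """
    _require_converged(fit)
    n = bundle.n
    if B.is_identity:
        value = (float(fit.mu_g @ fit.mu_g) + fit.trace_cov_g_given_y()) / (n - 1)
        name: Estimator = "W"
        population = "current"
    else:
        M = np.outer(fit.mu_g, fit.mu_g) + fit.cov_g_given_y
        value = float(np.sum(B.matrix * M)) / (n - 1)
        name = "W_s_star" if B.transform_source == "grm" else "W_star"
        population = "base"
    if B.is_identity and bundle.p <= verify_cap and np.isfinite(fit.vc.sigma_b2):
        mf = _marker_form_bp(fit, B, bundle)
        scale = max(abs(value), abs(mf), 1.0)
        if abs(value - mf) > 1e-9 * scale:
            raise AssertionError(
                f"marker-form and equivalent-model BP disagree: {mf} vs {value}"
            )
    v_match = unconditional_expectation(fit, B, bundle).value
    return VariancePrediction(name, population, value, value - v_match, B.transform_source, n)


def _marker_form_bp(fit: GblupFit, B: BMatrix, bundle: GrmBundle) -> float:
    """tr(SigmaHat [mu_beta mu_beta' + Sigma_{beta|y}]) via dense p x p pieces."""
    blups = marker_blups(fit, bundle, cap=max(bundle.p, 1))
    # base-population marker-form checks go through base_design() in tests,
    # since R^{-1/2} cannot be recovered from B alone
    C = bundle.centered
    S = marker_covariance(C, "current", cap=C.shape[1]).matrix
    M = np.outer(blups.mu_beta, blups.mu_beta) + blups.cov_beta_given_y
    return float(np.sum(S * M))


@dataclass
class LdContribution:
    value: float
    diagonal: float | None = None       # variance-weighted partial sum
    off_diagonal: float | None = None   # LD-weighted partial sum
    population: Literal["current", "base"] = "current"


def ld_contribution(
    fit: GblupFit,
    bundle: GrmBundle,
    population: Literal["current", "base"] = "current",
    R: RelationshipMatrix | np.ndarray | None = None,
    explicit: bool = False,
    breakdown: bool = False,
    cap: int = DEFAULT_P_CAP,
) -> LdContribution:
    """The LD contribution L(y) = BP(s^2_{g,B}) - E[s^2_{g,B}].

    Default path: the exact identity W - V (O(n^2), any p). With
    ``explicit=True`` (or ``breakdown=True``) the printed double sum

        L(y) = sum_j [mm' - Cov(mu_beta)]_jj (SigmaHat)_jj
             + sum_{i != j} [mm' - Cov(mu_beta)]_ij (SigmaHat)_ij

    is evaluated instead (p <= cap required), optionally split into its
    diagonal and off-diagonal partial sums.
    """
    _require_converged(fit)
    if population == "base" and R is None:
        raise DataError("base-population L(y) requires a relationship matrix")
    if not (explicit or breakdown):
        B = make_B(population, R=R) if population == "base" else make_B("current")
        w = best_predictor(fit, B, bundle)
        return LdContribution(value=w.ld_component, population=population)
    if bundle.p > cap:
        raise DataError(f"explicit L(y) sum requires p <= {cap}")
    blups = marker_blups(fit, bundle, cap=cap)
    weights = np.outer(blups.mu_beta, blups.mu_beta) - blups.cov_mu_beta
    C = bundle.centered if population == "current" else base_design(bundle, R)
    S = marker_covariance(C, population, cap=cap).matrix
    prod = weights * S
    diag = float(np.trace(prod))
    total = float(prod.sum())
    return LdContribution(value=total, diagonal=diag, off_diagonal=total - diag,
                          population=population)


def heritability_summary(
    fit: GblupFit,
    V: VariancePrediction,
    W: VariancePrediction,
    y: PhenotypeVector | np.ndarray,
) -> HeritabilitySummary:
    """Genomic heritabilities from current-population V and W.

    h2 = estimate / phenotypic sample variance, and the alternative
    definition h2~ = estimate / (estimate + sigma_e^2). The base population
    has no heritability: the residual variance refers to the current one.
    """
    if V.population != "current" or W.population != "current":
        raise DataError("heritability is defined only in the current population")
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    s2y = float(np.var(yv, ddof=1))
    s2e = fit.vc.sigma_e2
    return HeritabilitySummary(
        h2_V=V.value / s2y,
        h2_W=W.value / s2y,
        h2_tilde_V=V.value / (V.value + s2e),
        h2_tilde_W=W.value / (W.value + s2e),
        phenotypic_variance=s2y,
    )


def estimate(
    fit: GblupFit,
    bundle: GrmBundle,
    estimator: Estimator,
    R: RelationshipMatrix | np.ndarray | None = None,
    rank_tol: float | None = None,
) -> VariancePrediction:
    """Dispatch a single named estimator.

    ``V``/``W`` need no relationship matrix; ``V_star``/``W_star`` require
    one; ``V_s_star``/``W_s_star`` use the GRM itself for the base
    transformation (Vs* collapses to sigma_g^2, the variance component that
    GREML-style analyses report as the genomic variance).
    """
    _require_converged(fit)
    if estimator == "V":
        return unconditional_expectation(fit, make_B("current"), bundle)
    if estimator == "W":
        return best_predictor(fit, make_B("current"), bundle)
    if estimator in ("V_star", "W_star"):
        if R is None:
            raise DataError(f"{estimator} requires a relationship matrix")
        B = make_B("base", R=R, rank_tol=rank_tol)
        if estimator == "V_star":
            return unconditional_expectation(fit, B, bundle)
        return best_predictor(fit, B, bundle)
    if estimator == "V_s_star":
        return VariancePrediction("V_s_star", "base", fit.vc.sigma_g2, None, "grm", bundle.n)
    if estimator == "W_s_star":
        B = make_B("base", use_grm=True, G=bundle, rank_tol=rank_tol)
        return best_predictor(fit, B, bundle)
    raise ValueError(f"unknown estimator {estimator!r}")
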