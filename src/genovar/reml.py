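"""Spectral profile REML for the gBLUP model and its BLUP machinery.

Model:  y = mu*1 + g + eps,  g ~ N(0, sigma_g^2 G),  eps ~ N(0, sigma_e^2 I).

With G = U diag(d) U' eigendecomposed once, the restricted likelihood of the
variance ratio lambda = sigma_g^2 / sigma_e^2 profiles out both mu and
sigma_e^2, leaving a 1-D optimization on log(lambda). Every likelihood
evaluation is O(n) after the rotation of (y, 1) into the eigenbasis, which
makes repeated fits on the same G (simulation replicates) essentially free.

The fit exposes the BLUP of the genomic values, mu_{g|y} = sigma_g^2 G Q y,
its covariance Cov(mu_{g|y}) = sigma_g^4 G Q G, and the conditional
covariance Sigma_{g|y} = sigma_g^2 G - Cov(mu_{g|y}), where
Q = V^{-1} - V^{-1} 1 (1'V^{-1}1)^{-1} 1'V^{-1} is the REML projection that
accounts for estimating the intercept. Marker-effect analogues follow from
mu_{beta|y} = sigma_b^2 (PX)' Q y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

from genovar.grm import DEFAULT_P_CAP, GrmBundle
from genovar.io import DataError, PhenotypeVector

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitOptions:
    """Convergence configuration for the profile-REML optimizer."""

    lambda_bounds: tuple[float, float] = (1e-8, 1e8)
    log_lambda_tol: float = 1e-10
    max_iter: int = 500
    psd_tol: float = 1e-8  # relative floor for negative eigenvalues of G


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    sigma_b2: float          # sigma_g2 / c; NaN when no marker scaling known
    mu: float
    loglik_restricted: float
    converged: bool
    n_iter: int
    boundary: bool = False   # sigma_g2 pinned at 0


class EigenGRM:
    """Cached eigendecomposition of a GRM, reusable across fits on the same G."""

    def __init__(self, G: np.ndarray, psd_tol: float = 1e-8):
        G = np.asarray(G, dtype=float)
        d, U = np.linalg.eigh(G)
        scale = max(d[-1], 0.0)
        if scale > 0 and d[0] < -psd_tol * scale:
            raise DataError(
                f"G is not positive semidefinite: min eigenvalue {d[0]:.3e} "
                f"(max {scale:.3e})"
            )
        self.d = np.clip(d, 0.0, None)
        self.U = U
        n = G.shape[0]
        self.ones_rot = U.T @ np.ones(n)

    @property
    def n(self) -> int:
        return self.d.size


def _profile(lam: float, d: np.ndarray, ot: np.ndarray, yt: np.ndarray) -> tuple[float, float, float]:
    """Profiled restricted log-likelihood at variance ratio lam.

    Returns (loglik, mu_hat, sigma_e2_hat). O(n).
    """
    n = d.size
    h = lam * d + 1.0
    a = float(np.sum(ot * ot / h))          # 1' H^-1 1
    b = float(np.sum(ot * yt / h))          # 1' H^-1 y
    yy = float(np.sum(yt * yt / h))         # y' H^-1 y
    mu = b / a
    yqy = yy - b * b / a                    # y' Q_H y
    if yqy <= 0:
        return -np.inf, mu, 0.0
    s2e = yqy / (n - 1)
    ll = -0.5 * ((n - 1) * (np.log(s2e) + 1.0 + _LOG2PI)
                 + float(np.sum(np.log(h))) + np.log(a))
    return ll, mu, s2e


@dataclass
class GblupFit:
    """A converged REML fit plus everything needed for BLUPs and predictors.

    Dense n x n conditional covariances are assembled lazily; the trace
    accessors avoid them entirely and are O(n).
    """

    vc: VarianceComponents
    eigen: EigenGRM
    c: float | None                      # marker scaling constant, if known
    y: np.ndarray
    _lam: float = field(repr=False, default=0.0)
    _h: np.ndarray = field(repr=False, default=None)
    _w: np.ndarray = field(repr=False, default=None)   # rotated H^-1 (y - mu 1)
    profile_trace: list[tuple[float, float]] = field(default_factory=list, repr=False)

    @property
    def n(self) -> int:
        return self.eigen.n

    # -- BLUP of genomic values ------------------------------------------

    @cached_property
    def mu_g(self) -> np.ndarray:
        """BLUP mu_{g|y} = sigma_g^2 G Q y = lambda U (d * w)."""
        return self.eigen.U @ (self._lam * self.eigen.d * self._w)

    @cached_property
    def _qrot(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Pieces of the rotated REML projection Q (without the 1/sigma_e2)."""
        ot = self.eigen.ones_rot
        a = float(np.sum(ot * ot / self._h))
        return 1.0 / self._h, ot / self._h, a

    def Qy(self) -> np.ndarray:
        """Q y = V^{-1}(y - mu 1) as an n-vector."""
        return self.eigen.U @ (self._w / self.vc.sigma_e2)

    def apply_Q(self, M: np.ndarray) -> np.ndarray:
        """Q @ M for an n x m block, in O(n^2 m)."""
        hinv, oh, a = self._qrot
        Mr = self.eigen.U.T @ M
        out = Mr * hinv[:, None] - np.outer(oh, (oh @ Mr) / a)
        return (self.eigen.U @ out) / self.vc.sigma_e2

    @cached_property
    def cov_mu_g(self) -> np.ndarray:
        """Cov(mu_{g|y}) = sigma_g^4 G Q G (dense n x n)."""
        hinv, oh, a = self._qrot
        d = self.eigen.d
        core = np.diag(d * d * hinv) - np.outer(d * oh, d * oh) / a
        M = (self.vc.sigma_g2 ** 2 / self.vc.sigma_e2) * (self.eigen.U @ core @ self.eigen.U.T)
        return 0.5 * (M + M.T)

    @cached_property
    def cov_g_given_y(self) -> np.ndarray:
        """Sigma_{g|y} = sigma_g^2 G - Cov(mu_{g|y}) (dense n x n)."""
        G = self.eigen.U @ (self.eigen.d[:, None] * self.eigen.U.T)
        M = self.vc.sigma_g2 * G - self.cov_mu_g
        return 0.5 * (M + M.T)

    def trace_cov_mu_g(self) -> float:
        hinv, oh, a = self._qrot
        d = self.eigen.d
        t = float(np.sum(d * d * hinv) - np.sum((d * oh) ** 2) / a)
        return self.vc.sigma_g2 ** 2 / self.vc.sigma_e2 * t

    def trace_cov_g_given_y(self) -> float:
        return self.vc.sigma_g2 * float(np.sum(self.eigen.d)) - self.trace_cov_mu_g()


def fit_gblup(
    y: PhenotypeVector | np.ndarray,
    grm: GrmBundle | np.ndarray | EigenGRM,
    options: FitOptions | None = None,
    scaling_c: float | None = None,
) -> GblupFit:
    """REML fit of the two-component gBLUP model with an intercept.

    Accepts a :class:`GrmBundle`, a raw G matrix, or a precomputed
    :class:`EigenGRM` (to amortize the eigendecomposition over replicated
    fits). The variance ratio is optimized on the log scale by bounded
    derivative-free minimization; the sigma_g^2 = 0 boundary is checked
    explicitly and reported with ``boundary=True`` rather than as an error.
    """
    opts = options or FitOptions()
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    c = scaling_c
    if isinstance(grm, EigenGRM):
        eig = grm
    elif isinstance(grm, GrmBundle):
        eig = EigenGRM(grm.G, opts.psd_tol)
        c = grm.c if c is None else c
    else:
        eig = EigenGRM(np.asarray(grm, dtype=float), opts.psd_tol)
    n = eig.n
    if yv.size != n:
        raise DataError(f"phenotype length {yv.size} does not match G ({n})")
    if np.var(yv, ddof=1) <= 0:
        raise DataError("phenotype is constant; variance components undefined")

    d, U, ot = eig.d, eig.U, eig.ones_rot
    yt = U.T @ yv
    trace: list[tuple[float, float]] = []

    ll0, mu0, s2e0 = _profile(0.0, d, ot, yt)

    if d.max() <= 0.0:
        # G = 0: no genomic signal representable; null model is exact
        lam, ll, mu, s2e, converged, n_iter, boundary = 0.0, ll0, mu0, s2e0, True, 0, True
    else:
        lo, hi = opts.lambda_bounds

        def neg_ll(t: float) -> float:
            ll, _, _ = _profile(float(np.exp(t)), d, ot, yt)
            trace.append((float(np.exp(t)), ll))
            return -ll

        res = minimize_scalar(
            neg_ll,
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": opts.log_lambda_tol, "maxiter": opts.max_iter},
        )
        if not res.success:
            raise RuntimeError(
                f"REML did not converge in {opts.max_iter} iterations; "
                f"profile trace: {trace[-5:]}"
            )
        lam = float(np.exp(res.x))
        ll, mu, s2e = _profile(lam, d, ot, yt)
        n_iter = int(res.nfev)
        converged = True
        boundary = False
        if ll0 >= ll:
            lam, ll, mu, s2e, boundary = 0.0, ll0, mu0, s2e0, True
        elif lam <= lo * 1.05:
            boundary = True

    s2g = lam * s2e
    vc = VarianceComponents(
        sigma_g2=s2g,
        sigma_e2=s2e,
        sigma_b2=(s2g / c) if c else float("nan"),
        mu=mu,
        loglik_restricted=ll,
        converged=converged,
        n_iter=n_iter,
        boundary=boundary,
    )
    h = lam * d + 1.0
    w = (yt - ot * mu) / h
    return GblupFit(vc=vc, eigen=eig, c=c, y=yv, _lam=lam, _h=h, _w=w,
                    profile_trace=trace)


@dataclass
class MarkerBlups:
    """BLUP of marker effects and its (possibly implicit) covariances."""

    mu_beta: np.ndarray
    cov_mu_beta: np.ndarray | None       # sigma_b^4 (PX)' Q (PX), p x p
    cov_beta_given_y: np.ndarray | None  # sigma_b^2 I - cov_mu_beta
    sigma_b2: float
    materialized: bool


def marker_blups(fit: GblupFit, bundle: GrmBundle, cap: int = DEFAULT_P_CAP) -> MarkerBlups:
    """Marker-effect BLUP mu_{beta|y} = sigma_b^2 (PX)' Q y and covariances.

    The p x p covariance matrices are materialized only for p <= cap;
    above the cap only the p-vector BLUP is returned (``materialized`` is
    False) and callers must work in the n-dimensional representation.
    """
    if not fit.vc.converged:
        raise RuntimeError("fit did not converge")
    Z = bundle.centered
    s2b = fit.vc.sigma_b2
    mu_beta = s2b * (Z.T @ fit.Qy())
    p = Z.shape[1]
    if p > cap:
        return MarkerBlups(mu_beta, None, None, s2b, False)
    QZ = fit.apply_Q(Z)
    cov_mu = s2b ** 2 * (Z.T @ QZ)
    cov_mu = 0.5 * (cov_mu + cov_mu.T)
    cov_cond = s2b * np.eye(p) - cov_mu
    return MarkerBlups(mu_beta, cov_mu, cov_cond, s2b, True)
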