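"""Transformation to the base population and the quadratic-form matrix B.

The observed (current) population may contain related individuals. The
decorrelated genomic values g* = R^{-1/2} g refer to the hypothetical
unrelated base population, where R is a supplied (pedigree or genomic)
relationship matrix. The additive genomic variance in either population is
the quadratic form s^2_{g,B} = g' B g / (n-1) with

    B = I                      (current population)
    B = R^{-1/2} P R^{-1/2}    (base population)

When no pedigree matrix exists, the GRM itself can serve as R. G is
singular by construction (G 1 = 0), so its inverse square root is taken in
the Moore-Penrose sense: eigenvalues below ``rank_tol * lambda_max`` are
treated as exact zeros and inverted to zero, making R^{-1/2} R R^{-1/2} the
orthogonal projector onto range(R).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from genovar.grm import GrmBundle
from genovar.io import DataError, RelationshipMatrix


def inverse_sqrt(R: RelationshipMatrix | np.ndarray, rank_tol: float | None = None) -> np.ndarray:
    """Pseudo-inverse square root of a symmetric PSD matrix.

    ``rank_tol`` is relative to the largest eigenvalue; default is
    ``n * machine epsilon``. Eigenvalues in ``[-tol, tol]`` are zeroed
    (Moore-Penrose); eigenvalues below ``-tol`` are an error.
    """
    Rm = R.values if isinstance(R, RelationshipMatrix) else np.asarray(R, dtype=float)
    n = Rm.shape[0]
    if rank_tol is None:
        rank_tol = n * np.finfo(float).eps
    lam, U = np.linalg.eigh(0.5 * (Rm + Rm.T))
    lmax = max(lam[-1], 0.0)
    tol = rank_tol * lmax if lmax > 0 else rank_tol
    if lam[0] < -tol:
        raise DataError(
            f"matrix has negative eigenvalue {lam[0]:.3e} beyond tolerance {tol:.3e}"
        )
    inv_sqrt = np.where(lam > tol, 1.0 / np.sqrt(np.clip(lam, tol, None)), 0.0)
    M = (U * inv_sqrt) @ U.T
    return 0.5 * (M + M.T)


@dataclass
class BMatrix:
    """The PSD matrix selecting the target population in g'Bg/(n-1)."""

    population: Literal["current", "base"]
    matrix: np.ndarray | None = None     # None <=> identity tag (current)
    transform_source: Literal["none", "supplied_R", "grm"] = "none"

    @property
    def is_identity(self) -> bool:
        return self.matrix is None

    def __post_init__(self) -> None:
        if self.population == "current" and self.matrix is not None:
            raise DataError("current population uses the identity B")
        if self.population == "base" and self.matrix is None:
            raise DataError("base population requires an explicit B matrix")


def _centering(n: int) -> np.ndarray:
    return np.eye(n) - np.full((n, n), 1.0 / n)


def make_B(
    population: Literal["current", "base"],
    R: RelationshipMatrix | np.ndarray | None = None,
    use_grm: bool = False,
    G: GrmBundle | np.ndarray | None = None,
    rank_tol: float | None = None,
) -> BMatrix:
    """Build the quadratic-form matrix for the requested population.

    Current population: identity (stored as a tag, never materialized).
    Base population: ``R^{-1/2} P R^{-1/2}`` from a supplied relationship
    matrix, or from the GRM (``use_grm=True``) via its pseudo-inverse square
    root restricted to range(G).
    """
    if population == "current":
        return BMatrix(population="current")
    if R is not None:
        Rm = R.values if isinstance(R, RelationshipMatrix) else np.asarray(R, dtype=float)
        src = "supplied_R"
    elif use_grm:
        if G is None:
            raise DataError("use_grm requires the GRM bundle")
        Rm = G.G if isinstance(G, GrmBundle) else np.asarray(G, dtype=float)
        src = "grm"
    else:
        raise DataError("base population requires a relationship matrix or use_grm")
    Rinv = inverse_sqrt(Rm, rank_tol)
    n = Rinv.shape[0]
    B = Rinv @ _centering(n) @ Rinv
    return BMatrix(population="base", matrix=0.5 * (B + B.T), transform_source=src)


def base_design(bundle: GrmBundle, R: RelationshipMatrix | np.ndarray,
                rank_tol: float | None = None) -> np.ndarray:
    """Centered base-population design ``P X* = P R^{-1/2} (PX)``.

    Used for the marker-form cross-checks (SigmaHat_{X*} and the explicit
    L(y) sums); O(n^2 p), so only sensible below the materialization cap.
    """
    Rinv = inverse_sqrt(R, rank_tol)
    Xstar = Rinv @ bundle.centered
    return Xstar - Xstar.mean(axis=0)
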