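"""Genotype centering, allele-frequency scaling and the genomic relationship matrix.

The GRM follows the VanRaden convention

    G = P X X' P / c,      c = 2 * sum_j p_j (1 - p_j),

where ``P = I - 11'/n`` centers columns and ``p_j`` is the minor-allele
frequency of marker j estimated from the sample (column mean / 2, folded to
``min(p, 1-p)``). Monomorphic markers carry no variance and are dropped with
a warning before G is formed.

The marker sample covariance ``SigmaHat_X = X' P X / (n - 1)`` is exposed
either as an explicit p x p matrix or, above a configurable size cap, as an
implicit operator backed by the centered genotypes, so that traces and
quadratic forms stay O(n p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from genovar.io import DataError, GenotypeMatrix

logger = logging.getLogger("genovar")

#: default ceiling on markers for materializing p x p matrices
DEFAULT_P_CAP = 20_000


def center_columns(X: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center the columns of a genotype matrix.

    Returns ``(PX, col_means)`` where ``col_means[j] = 2 * p_j`` (twice the
    counted-allele frequency). Requires at least two samples, otherwise the
    centering matrix P is degenerate.
    """
    vals = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    if vals.shape[0] < 2:
        raise DataError("centering needs n >= 2 samples")
    if np.isnan(vals).any():
        raise DataError("genotypes contain missing values; impute or filter first")
    col_means = vals.mean(axis=0)
    return vals - col_means, col_means


def scaling_constant(allele_freqs: np.ndarray) -> float:
    """VanRaden scaling constant ``c = 2 * sum_j p_j (1 - p_j)``.

    ``allele_freqs`` are minor-allele frequencies in [0, 0.5]; monomorphic
    markers (p = 0) contribute nothing. All-monomorphic input gives c = 0
    and is an error.
    """
    p = np.asarray(allele_freqs, dtype=float)
    if ((p < 0) | (p > 0.5)).any():
        raise DataError("allele frequencies must lie in [0, 0.5] after folding")
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c <= 0.0:
        raise DataError("all markers are monomorphic (c = 0)")
    return c


@dataclass
class GrmBundle:
    """Centered genotypes, scaling constant and GRM for one sample set."""

    centered: np.ndarray            # n x p_kept, column means 0
    c: float                        # 2 sum p(1-p), dosage-variance units
    G: np.ndarray                   # n x n GRM
    allele_freqs: np.ndarray        # minor-allele freqs of kept markers
    marker_ids: list[str]
    sample_ids: list[str]
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.centered.shape[0]

    @property
    def p(self) -> int:
        return self.centered.shape[1]


def build_grm(X: GenotypeMatrix) -> GrmBundle:
    """Build the VanRaden GRM from raw dosages.

    Monomorphic columns are dropped (recorded in ``dropped_markers``);
    allele frequencies are folded to the minor allele. The GRM satisfies
    ``G 1 = 0`` because each centered column sums to zero.
    """
    centered, col_means = center_columns(X)
    freqs = col_means / 2.0
    folded = np.minimum(freqs, 1.0 - freqs)
    # zero sample variance marks a monomorphic column (this also catches an
    # all-heterozygote column, whose folded frequency is 0.5)
    poly = (centered ** 2).sum(axis=0) > 0.0
    dropped = [m for m, keep in zip(X.marker_ids, poly) if not keep]
    if dropped:
        logger.warning("dropping %d monomorphic marker(s): %s", len(dropped), dropped[:5])
    if not poly.any():
        raise DataError("all markers are monomorphic (c = 0)")
    centered = np.ascontiguousarray(centered[:, poly])
    folded = folded[poly]
    c = scaling_constant(folded)
    G = centered @ centered.T / c
    G = 0.5 * (G + G.T)
    return GrmBundle(
        centered=centered,
        c=c,
        G=G,
        allele_freqs=folded,
        marker_ids=[m for m, keep in zip(X.marker_ids, poly) if keep],
        sample_ids=list(X.sample_ids),
        dropped_markers=dropped,
    )


@dataclass
class MarkerCovariance:
    """Sample covariance of marker genotypes, explicit or implicit.

    Explicit form stores the p x p matrix ``C'C/(n-1)`` where C is the
    centered design. The implicit form keeps only C and answers traces and
    quadratic forms through it, which is exact and O(n p).
    """

    population: Literal["current", "base"]
    matrix: np.ndarray | None = None
    centered: np.ndarray | None = None  # C with SigmaHat = C'C/(n-1)
    n: int = 0

    @property
    def materialized(self) -> bool:
        return self.matrix is not None

    def trace(self) -> float:
        if self.matrix is not None:
            return float(np.trace(self.matrix))
        return float(np.sum(self.centered ** 2) / (self.n - 1))

    def quadratic_form(self, beta: np.ndarray) -> float:
        """``beta' SigmaHat beta``, evaluated as ``||C beta||^2/(n-1)`` implicitly."""
        if self.matrix is not None:
            return float(beta @ self.matrix @ beta)
        v = self.centered @ beta
        return float(v @ v / (self.n - 1))


def marker_covariance(
    centered: np.ndarray,
    population: Literal["current", "base"] = "current",
    cap: int = DEFAULT_P_CAP,
) -> MarkerCovariance:
    """``SigmaHat = C'C/(n-1)`` for an already centered design C.

    For the base population pass ``C = P X*`` (the re-centered transformed
    design). The p x p matrix is materialized only for ``p <= cap``.
    """
    centered = np.asarray(centered, dtype=float)
    n, p = centered.shape
    if p <= cap:
        mat = centered.T @ centered / (n - 1)
        return MarkerCovariance(population=population, matrix=0.5 * (mat + mat.T),
                                centered=centered, n=n)
    return MarkerCovariance(population=population, matrix=None, centered=centered, n=n)
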