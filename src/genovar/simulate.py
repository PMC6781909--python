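"""Synthetic genotype/phenotype generation under the random-effects model.

Generates exactly the data-generating process the estimators assume:
dosage genotypes in {0,1,2}, i.i.d. normal marker effects
beta_j ~ N(0, sigma_b^2), and additive phenotypes

    y = mu*1 + P X beta + eps,   eps ~ N(0, sigma_e^2 I).

Two LD regimes:

* ``independent`` — Binomial(2, p_j) dosages, no LD;
* ``ar1_haplotype`` — each individual is the sum of two independent
  haplotypes, each a first-order Markov chain over loci with exact
  Bernoulli(p_j) marginals and adjacent-locus correlation rho. Because the
  two haplotypes are independent, the adjacent-marker *dosage* correlation
  is also rho. For unequal MAFs the target correlation can exceed the
  Frechet bound for a pair of Bernoullis; the chain then clips that pair to
  0.999 of its maximum (with constant MAF no clipping ever occurs).

The realized additive genomic variance s_g^2 = beta' SigmaHat_X beta is
stored with every dataset so tests can compare predictors against the
random target they aim at.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from genovar.io import DataError, GenotypeMatrix, PhenotypeVector, RelationshipMatrix


@dataclass
class LdConfig:
    model: Literal["independent", "ar1_haplotype"] = "independent"
    rho: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeVector
    true_beta: np.ndarray
    true_sigma_b2: float
    true_sigma_e2: float
    true_mu: float
    realized_sg2: float                      # beta' SigmaHat_X beta
    realized_sg_star2: float | None = None   # base-population analogue
    relationship: RelationshipMatrix | None = None
    seed: int | None = None
    ld_config: LdConfig | None = None


def simulate_genotypes(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    ld_model: Literal["independent", "ar1_haplotype"] = "independent",
    rho: float = 0.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate dosage genotypes with a tunable MAF spectrum and adjacent LD."""
    if n < 2 or p < 1:
        raise DataError("need n >= 2 and p >= 1")
    if not (0.0 <= rho < 1.0):
        raise DataError("rho must be in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise DataError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=p) if lo < hi else np.full(p, lo)
    if ld_model == "independent" or rho == 0.0:
        dosages = rng.binomial(2, mafs, size=(n, p)).astype(float)
    elif ld_model == "ar1_haplotype":
        dosages = (_haplotypes(rng, n, mafs, rho) + _haplotypes(rng, n, mafs, rho)).astype(float)
    else:
        raise DataError(f"unknown ld_model {ld_model!r}")
    sample_ids = [f"s{i:05d}" for i in range(n)]
    marker_ids = [f"m{j:05d}" for j in range(p)]
    return GenotypeMatrix(dosages, sample_ids, marker_ids)


def _haplotypes(rng: np.random.Generator, n: int, mafs: np.ndarray, rho: float) -> np.ndarray:
    """First-order Markov haplotypes with Bernoulli(p_j) marginals.

    For each adjacent pair the joint P(1,1) is set to
    p1 p2 + r sqrt(p1 q1 p2 q2) with r = min(rho, 0.999 rho_max), which
    keeps the marginals exact and the pairwise correlation equal to r.
    """
    p = mafs.size
    H = np.empty((n, p), dtype=np.int8)
    H[:, 0] = rng.random(n) < mafs[0]
    for j in range(1, p):
        p1, p2 = mafs[j - 1], mafs[j]
        q1, q2 = 1.0 - p1, 1.0 - p2
        sd = np.sqrt(p1 * q1 * p2 * q2)
        rho_max = (min(p1, p2) - p1 * p2) / sd
        r = min(rho, 0.999 * rho_max)
        p11 = p1 * p2 + r * sd
        t1 = p11 / p1               # P(h_j = 1 | h_{j-1} = 1)
        t0 = (p2 - p11) / q1        # P(h_j = 1 | h_{j-1} = 0)
        u = rng.random(n)
        H[:, j] = np.where(H[:, j - 1] == 1, u < t1, u < t0)
    return H


def ar1_adjacent_correlation(mafs: np.ndarray, rho: float) -> np.ndarray:
    """Analytic adjacent-marker dosage correlations of the haplotype chain.

    Equals rho wherever the Frechet bound allows it; clipped pairs return
    their clipped value. Dosage correlation equals haplotype correlation
    because the two haplotypes are independent.
    """
    mafs = np.asarray(mafs, dtype=float)
    out = np.empty(mafs.size - 1)
    for j in range(1, mafs.size):
        p1, p2 = mafs[j - 1], mafs[j]
        sd = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        rho_max = (min(p1, p2) - p1 * p2) / sd
        out[j - 1] = min(rho, 0.999 * rho_max)
    return out


def simulate_phenotypes(
    X: GenotypeMatrix,
    sigma_b2: float,
    sigma_e2: float,
    mu: float = 0.0,
    seed: int | None = None,
    relationship: RelationshipMatrix | None = None,
    ld_config: LdConfig | None = None,
) -> SyntheticDataset:
    """Draw beta ~ N(0, sigma_b2 I), eps ~ N(0, sigma_e2 I) and form y.

    Stores the realized additive genomic variance s_g^2 = ||PX beta||^2 /
    (n-1) and, when a relationship matrix is attached, the base-population
    analogue s_g*^2 = (g*)' P g* / (n-1) with g* = R^{-1/2} P X beta.
    """
    if sigma_b2 < 0 or sigma_e2 <= 0:
        raise DataError("need sigma_b2 >= 0 and sigma_e2 > 0")
    rng = np.random.default_rng(seed)
    n, p = X.values.shape
    beta = rng.normal(0.0, np.sqrt(sigma_b2), size=p) if sigma_b2 > 0 else np.zeros(p)
    eps = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    centered = X.values - X.values.mean(axis=0)
    g = centered @ beta
    y = mu + g + eps
    sg2 = float(g @ g / (n - 1))
    sg_star2 = None
    if relationship is not None:
        from genovar.basepop import inverse_sqrt  # local import avoids a cycle
        gstar = inverse_sqrt(relationship) @ g
        gc = gstar - gstar.mean()
        sg_star2 = float(gc @ gc / (n - 1))
    return SyntheticDataset(
        genotypes=X,
        phenotypes=PhenotypeVector(y, list(X.sample_ids)),
        true_beta=beta,
        true_sigma_b2=float(sigma_b2),
        true_sigma_e2=float(sigma_e2),
        true_mu=float(mu),
        realized_sg2=sg2,
        realized_sg_star2=sg_star2,
        relationship=relationship,
        seed=seed,
        ld_config=ld_config,
    )


def make_relationship(
    kind: Literal["identity", "block_family"],
    n: int,
    block_size: int = 5,
    relatedness: float = 0.5,
    seed: int | None = None,
) -> RelationshipMatrix:
    """Simple PSD relationship structures for testing base-population paths.

    ``block_family`` tiles the diagonal with equicorrelated family blocks
    (1 on the diagonal, ``relatedness`` off it); PSD requires
    relatedness in [-1/(m-1), 1] for block size m.
    """
    ids = [f"s{i:05d}" for i in range(n)]
    if kind == "identity":
        return RelationshipMatrix(np.eye(n), ids, "pedigree")
    if kind != "block_family":
        raise DataError(f"unknown relationship kind {kind!r}")
    m = block_size
    if m < 1 or not (-1.0 / max(m - 1, 1) <= relatedness <= 1.0):
        raise DataError("relatedness outside the PSD range for this block size")
    R = np.eye(n)
    for start in range(0, n, m):
        stop = min(start + m, n)
        R[start:stop, start:stop] = relatedness
        np.fill_diagonal(R[start:stop, start:stop], 1.0)
    return RelationshipMatrix(R, ids, "pedigree")


# ---------------------------------------------------------------------------
# fixture writers (the TSV formats io_formats reads)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write genotypes/phenotypes (and relationship, truth) as TSV/JSON fixtures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    g = ds.genotypes
    gdf = pd.DataFrame(g.values.astype(int), index=g.sample_ids, columns=g.marker_ids)
    paths["genotypes"] = out / "genotypes.tsv"
    gdf.to_csv(paths["genotypes"], sep="\t")
    paths["phenotypes"] = out / "phenotypes.tsv"
    pd.DataFrame({"id": ds.phenotypes.sample_ids, "y": ds.phenotypes.values}).to_csv(
        paths["phenotypes"], sep="\t", index=False, header=False
    )
    if ds.relationship is not None:
        rdf = pd.DataFrame(ds.relationship.values, index=ds.relationship.sample_ids,
                           columns=ds.relationship.sample_ids)
        paths["relationship"] = out / "relationship.tsv"
        rdf.to_csv(paths["relationship"], sep="\t")
    import json

    truth = {
        "seed": ds.seed,
        "mu": ds.true_mu,
        "sigma_b2": ds.true_sigma_b2,
        "sigma_e2": ds.true_sigma_e2,
        "realized_sg2": ds.realized_sg2,
        "realized_sg_star2": ds.realized_sg_star2,
        "ld_config": None if ds.ld_config is None else {
            "model": ds.ld_config.model,
            "rho": ds.ld_config.rho,
            "maf_range": list(ds.ld_config.maf_range),
        },
    }
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
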