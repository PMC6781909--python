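"""Reading and writing of genotype, phenotype, relationship and report files.

Formats
-------
* Genotypes: delimited text (samples x markers; first row marker IDs, first
  column sample IDs) or PLINK ``.raw`` (whitespace-delimited, six leading
  metadata columns, marker headers carry a counted-allele suffix ``_A``).
  Dosages must be 0/1/2; missing values (``NA``/empty) are kept as NaN at
  read time and either mean-imputed on request or rejected downstream.
* Phenotypes: two-column TSV ``sample_id<TAB>value`` (optional header).
* Relationship matrix: square TSV with sample IDs as header row and first
  column; checked for symmetry and absence of NaN.
* Reports: nested JSON (full double precision) or flat TSV, one row per
  estimator.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("genovar")

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix (n samples x p markers), entries in {0,1,2}.

    Missing entries are stored as NaN; they are only permitted transiently
    (between reading and imputation/validation).
    """

    values: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.marker_ids) != p:
            raise DataError("ID labels do not match genotype matrix shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.marker_ids, "marker")
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DataError(
                f"invalid dosage {self.values[i, j]!r} at sample "
                f"{self.sample_ids[i]!r}, marker {self.marker_ids[j]!r}; "
                "expected 0, 1 or 2"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def impute_mean(self) -> "GenotypeMatrix":
        """Replace missing dosages by their column mean.

        Mean imputation leaves the centered column sum at zero, so the
        sample mean of genomic values stays 0 after centering.
        """
        vals = self.values.copy()
        col_mean = np.nanmean(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals[idx] = col_mean[idx[1]]
        out = object.__new__(GenotypeMatrix)  # skip {0,1,2} re-validation
        out.values = vals
        out.sample_ids = list(self.sample_ids)
        out.marker_ids = list(self.marker_ids)
        return out


@dataclass
class PhenotypeVector:
    values: np.ndarray
    sample_ids: list[str]
    scaled_to_unit_variance: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.sample_ids) != self.values.size:
            raise DataError("phenotype IDs do not match vector length")
        _check_unique(self.sample_ids, "sample")
        if np.isnan(self.values).any():
            raise DataError("phenotype vector contains NaN")

    @property
    def n(self) -> int:
        return self.values.size

    def scaled(self) -> "PhenotypeVector":
        """Return a copy scaled to unit sample variance (ddof=1)."""
        s2 = float(np.var(self.values, ddof=1))
        if s2 <= 0:
            raise DataError("cannot scale a constant phenotype")
        return PhenotypeVector(self.values / np.sqrt(s2), list(self.sample_ids), True)


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    sample_ids: list[str]
    source: Literal["pedigree", "genomic"] = "pedigree"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise DataError("relationship matrix must be square and match its IDs")
        _check_unique(self.sample_ids, "sample")
        if np.isnan(self.values).any():
            raise DataError("relationship matrix contains NaN")
        scale = max(np.abs(self.values).max(), 1.0)
        if not np.allclose(self.values, self.values.T, rtol=0.0, atol=1e-10 * scale):
            raise DataError("relationship matrix is asymmetric beyond tolerance")
        # exact symmetrization so downstream eigh sees a symmetric array
        self.values = 0.5 * (self.values + self.values.T)


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dup = pd.Series(list(ids)).value_counts()
        dup = dup[dup > 1].index[0]
        raise DataError(f"duplicate {what} ID {dup!r}")


# ---------------------------------------------------------------------------
# readers


def read_genotypes(
    path: str | Path,
    format: Literal["tsv", "csv", "plink_raw"] = "tsv",
    impute_missing: bool = False,
) -> GenotypeMatrix:
    """Read a genotype dosage matrix.

    Parameters
    ----------
    path
        Input file.
    format
        ``tsv``/``csv``: samples x markers with marker IDs in the first row
        and sample IDs in the first column. ``plink_raw``: PLINK ``--recode A``
        output; the IID column provides sample IDs and the counted-allele
        suffix (``snp_A`` -> ``snp``) is stripped from marker IDs.
    impute_missing
        If true, missing dosages are replaced by the column mean; otherwise
        they are kept as NaN and rejected by downstream consumers.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", "nan", ""])
        sample_ids = [str(s) for s in df.index]
        marker_ids = [str(m) for m in df.columns]
        values = df.to_numpy(dtype=float)
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise DataError(f"PLINK .raw header lacks columns {missing_meta}")
        sample_ids = [str(s) for s in df["IID"]]
        geno = df.drop(columns=_PLINK_META)
        marker_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
        values = geno.to_numpy(dtype=float)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown genotype format {format!r}")
    gm = GenotypeMatrix(values, sample_ids, marker_ids)
    if impute_missing and gm.has_missing:
        gm = gm.impute_mean()
    return gm


def read_phenotypes(path: str | Path, delimiter: str = "\t") -> PhenotypeVector:
    """Read a two-column (sample_id, value) phenotype file."""
    df = pd.read_csv(path, sep=delimiter, header=None, comment="#")
    if df.shape[1] != 2:
        raise DataError(f"phenotype file must have 2 columns, found {df.shape[1]}")
    # tolerate a header line
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    ids = [str(s) for s in df.iloc[:, 0]]
    try:
        vals = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise DataError(f"non-numeric phenotype value: {exc}") from exc
    return PhenotypeVector(vals, ids)


def read_relationship(
    path: str | Path,
    source: Literal["pedigree", "genomic"] = "pedigree",
    delimiter: str = "\t",
) -> RelationshipMatrix:
    """Read a square relationship matrix with ID header row and column."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != ids:
        raise DataError("relationship matrix row and column IDs differ")
    return RelationshipMatrix(df.to_numpy(dtype=float), ids, source)


def read_matrix(path: str | Path, kind: Literal["phenotype", "relationship"], **kw):
    """Dispatch to :func:`read_phenotypes` or :func:`read_relationship`."""
    if kind == "phenotype":
        return read_phenotypes(path, **kw)
    if kind == "relationship":
        return read_relationship(path, **kw)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# alignment


def align(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    relationship: RelationshipMatrix | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector, RelationshipMatrix | None]:
    """Subset and reorder all inputs to the common sample set.

    The resulting order is sorted by sample ID so that downstream results do
    not depend on the input row order. Samples present in only some of the
    inputs are dropped with a logged warning.
    """
    common = set(genotypes.sample_ids) & set(phenotypes.sample_ids)
    if relationship is not None:
        common &= set(relationship.sample_ids)
    if not common:
        raise DataError("no samples shared between inputs")
    order = sorted(common)
    for obj, name in ((genotypes, "genotypes"), (phenotypes, "phenotypes")):
        dropped = set(obj.sample_ids) - common
        if dropped:
            logger.warning("dropping %d sample(s) absent elsewhere from %s: %s",
                           len(dropped), name, sorted(dropped)[:5])
    gi = [genotypes.sample_ids.index(s) for s in order]
    pi = [phenotypes.sample_ids.index(s) for s in order]
    g = GenotypeMatrix(genotypes.values[gi], order, list(genotypes.marker_ids))
    ph = PhenotypeVector(phenotypes.values[pi], order, phenotypes.scaled_to_unit_variance)
    rel = None
    if relationship is not None:
        ri = [relationship.sample_ids.index(s) for s in order]
        rel = RelationshipMatrix(relationship.values[np.ix_(ri, ri)], order, relationship.source)
    return g, ph, rel


# ---------------------------------------------------------------------------
# report


def write_report(report: dict, path: str | Path, format: Literal["json", "tsv"] = "json") -> None:
    """Serialize an analysis report.

    JSON keeps the full nested structure at double precision (``repr``
    round-trip). TSV flattens to one row per estimator, with the variance
    components repeated as columns.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    vc = report.get("variance_components", {})
    rows = []
    for est in report.get("estimates", []):
        row = {
            "estimator": est["estimator"],
            "population": est["population"],
            "value": est["value"],
            "ld_component": est.get("ld_component"),
        }
        row.update({f"vc_{k}": v for k, v in vc.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
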