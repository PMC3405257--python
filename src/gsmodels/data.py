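"""Genotype and phenotype containers, phenotype standardization, and text I/O.

Genotypes are biallelic marker dosages coded 0/1/2 (copies of a reference
allele).  Phenotypes arrive as replicated records per line; every model in
this package works on the standardized line mean

    ybar_i = (1 / (SD * n_i)) * sum_k y_ik

where ``n_i`` is the number of replicates of line *i* and ``SD`` is the
sample standard deviation of the within trait-by-environment line means.
The model residual for line *i* then has variance ``sigma2_eps / n_i``,
which the samplers honour through per-line weights ``n_i``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "CovariateMatrix",
    "PhenotypeRecords",
    "StandardizedPhenotypes",
    "GenotypeValidationError",
    "GenotypeParseError",
    "DegenerateInputError",
    "load_genotypes",
    "write_genotypes",
    "load_phenotypes",
    "write_phenotypes",
    "standardize_phenotypes",
]


class GenotypeParseError(ValueError):
    """A genotype file is structurally malformed (row length, header)."""


class GenotypeValidationError(ValueError):
    """A genotype entry is not a valid dosage in {0, 1, 2}."""


class DegenerateInputError(ValueError):
    """Input admits no well-defined answer (e.g. zero variance)."""


@dataclass
class CovariateMatrix:
    """A plain n x p real covariate matrix with line and column identifiers.

    Base container shared by raw dosages and derived covariates such as
    marker-by-marker products (values {0,1,2,4}); it performs shape and
    uniqueness checks only.
    """

    line_ids: list
    column_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        self.line_ids = [str(s) for s in self.line_ids]
        self.column_ids = [str(s) for s in self.column_ids]
        if len(self.line_ids) != n:
            raise ValueError(f"{len(self.line_ids)} line ids for {n} rows")
        if len(self.column_ids) != p:
            raise ValueError(f"{len(self.column_ids)} column ids for {p} columns")
        if len(set(self.line_ids)) != n:
            raise ValueError("line ids must be unique")
        if len(set(self.column_ids)) != p:
            raise ValueError("column ids must be unique")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix(CovariateMatrix):
    """n x p integer dosage matrix with entries in {0, 1, 2}.

    ``marker_ids`` aliases ``column_ids``.  Loading rejects anything outside
    {0,1,2}; missing values are either a hard error (strict, default) or
    mean-imputed and rounded back to the nearest dosage.
    """

    def __init__(self, line_ids, marker_ids, dosages):
        super().__init__(line_ids, marker_ids, np.asarray(dosages))
        bad = ~np.isin(self.values, (0, 1, 2))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise GenotypeValidationError(
                f"dosage {self.values[i, j]!r} at line {self.line_ids[i]!r}, "
                f"marker {self.column_ids[j]!r} is not in {{0,1,2}}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def marker_ids(self) -> list:
        return self.column_ids

    @property
    def dosages(self) -> np.ndarray:
        return self.values

    @property
    def n_markers(self) -> int:
        return self.n_columns


@dataclass
class PhenotypeRecords:
    """Replicated phenotype records for one trait-environment combination."""

    trait_env: str
    line_ids: list
    replicates: list  # list of 1-D arrays, one per line

    def __post_init__(self):
        self.line_ids = [str(s) for s in self.line_ids]
        if len(self.line_ids) != len(self.replicates):
            raise ValueError("one replicate array required per line")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line ids must be unique")
        self.replicates = [np.atleast_1d(np.asarray(r, dtype=float)) for r in self.replicates]
        for lid, r in zip(self.line_ids, self.replicates):
            if r.size == 0:
                raise DegenerateInputError(f"line {lid!r} has no replicates")
            if not np.all(np.isfinite(r)):
                raise ValueError(f"non-finite phenotype for line {lid!r}")

    @property
    def n_i(self) -> np.ndarray:
        """Replicate count per line."""
        return np.array([r.size for r in self.replicates], dtype=int)

    def line_means(self) -> np.ndarray:
        return np.array([r.mean() for r in self.replicates])


@dataclass
class StandardizedPhenotypes:
    """Standardized line means ready for model fitting.

    ``ybar`` has unit sample variance by construction; ``n_i`` carries the
    replicate counts for the sigma2_eps/n_i residual convention.
    """

    line_ids: list
    ybar: np.ndarray
    sd_used: float
    n_i: np.ndarray
    trait_env: str = ""

    def __post_init__(self):
        self.ybar = np.asarray(self.ybar, dtype=float)
        self.n_i = np.asarray(self.n_i, dtype=int)

    @property
    def n_lines(self) -> int:
        return self.ybar.size


def standardize_phenotypes(records: PhenotypeRecords) -> StandardizedPhenotypes:
    """Divide each within-line replicate mean by the SD of the line means.

    The SD uses the n-1 (sample) denominator.  Raises
    :class:`DegenerateInputError` when all line means are equal (SD = 0) or
    fewer than two lines are present.
    """
    means = records.line_means()
    if means.size < 2:
        raise DegenerateInputError("need at least two lines to standardize")
    sd = float(np.std(means, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("all line means are equal; SD = 0")
    return StandardizedPhenotypes(
        line_ids=list(records.line_ids),
        ybar=means / sd,
        sd_used=sd,
        n_i=records.n_i,
        trait_env=records.trait_env,
    )


# ---------------------------------------------------------------------------
# I/O: delimited text, comma or tab autodetected
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


_DOSAGE_RE = re.compile(r"^[012]$")


def load_genotypes(path, dialect: str = "auto", impute_missing: bool = False) -> GenotypeMatrix:
    """Read a genotype table: header row of marker ids, first column line ids.

    ``dialect`` is "auto" (sniff comma vs tab), "csv" or "tsv".  Missing
    cells (empty or NA) are a hard error unless ``impute_missing``, in which
    case they are replaced by the rounded marker mean.
    """
    sep = {"auto": _sniff_sep(path), "csv": ",", "tsv": "\t"}[dialect]
    rows, line_ids = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        marker_ids = header[1:]
        width = len(header)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split(sep)
            if len(parts) != width:
                raise GenotypeParseError(
                    f"{path}: row {lineno} has {len(parts)} fields, expected {width}"
                )
            line_ids.append(parts[0])
            rows.append(parts[1:])
    if not rows:
        raise GenotypeParseError(f"{path}: no data rows")

    mat = np.empty((len(rows), len(marker_ids)), dtype=float)
    missing = np.zeros_like(mat, dtype=bool)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan", "."):
                missing[i, j] = True
                mat[i, j] = np.nan
            elif _DOSAGE_RE.match(cell):
                mat[i, j] = int(cell)
            else:
                raise GenotypeValidationError(
                    f"{path}: value {cell!r} at row {i + 2}, column {j + 2} "
                    f"(line {line_ids[i]!r}, marker {marker_ids[j]!r}) is not in {{0,1,2}}"
                )
    if missing.any():
        if not impute_missing:
            i, j = map(int, np.argwhere(missing)[0])
            raise GenotypeValidationError(
                f"{path}: missing dosage at row {i + 2}, column {j + 2} "
                f"(line {line_ids[i]!r}, marker {marker_ids[j]!r}); "
                "pass impute_missing=True to mean-impute"
            )
        col_mean = np.nanmean(mat, axis=0)
        if np.isnan(col_mean).any():
            raise GenotypeValidationError(f"{path}: a marker column is entirely missing")
        fill = np.clip(np.rint(col_mean), 0, 2)
        mat = np.where(missing, fill[None, :], mat)
    return GenotypeMatrix(line_ids, marker_ids, mat.astype(int))


def write_genotypes(geno: GenotypeMatrix, path, sep: str = ",") -> None:
    df = pd.DataFrame(geno.dosages, index=geno.line_ids, columns=geno.marker_ids)
    df.to_csv(path, sep=sep, index_label="line_id")


def load_phenotypes(path, trait_env: str | None = None) -> PhenotypeRecords:
    """Read a long-format phenotype table (line_id, trait_env, replicate, value).

    When the file holds several trait-environment combinations, ``trait_env``
    selects one; with a single combination it may be omitted.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"line_id": str, "trait_env": str})
    required = {"line_id", "trait_env", "replicate", "value"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(f"{path}: phenotype file must have columns {sorted(required)}")
    combos = df["trait_env"].unique()
    if trait_env is None:
        if len(combos) != 1:
            raise ValueError(f"{path}: multiple trait_env values {list(combos)}; pick one")
        trait_env = combos[0]
    sub = df[df["trait_env"] == trait_env]
    if sub.empty:
        raise ValueError(f"{path}: no records for trait_env {trait_env!r}")
    line_ids, reps = [], []
    for lid, grp in sub.groupby("line_id", sort=False):
        line_ids.append(lid)
        reps.append(grp["value"].to_numpy(dtype=float))
    return PhenotypeRecords(trait_env=trait_env, line_ids=line_ids, replicates=reps)


def write_phenotypes(records: PhenotypeRecords, path) -> None:
    rows = []
    for lid, reps in zip(records.line_ids, records.replicates):
        for k, v in enumerate(reps, start=1):
            rows.append((lid, records.trait_env, k, v))
    pd.DataFrame(rows, columns=["line_id", "trait_env", "replicate", "value"]).to_csv(
        path, index=False
    )


def align_phenotypes(geno: GenotypeMatrix, pheno: StandardizedPhenotypes) -> StandardizedPhenotypes:
    """Reorder phenotypes to the genotype file's line order (join by line id).

    Unmatched ids on either side are a hard error.
    """
    index = {lid: k for k, lid in enumerate(pheno.line_ids)}
    missing = [lid for lid in geno.line_ids if lid not in index]
    if missing:
        raise ValueError(f"lines without phenotypes: {missing[:5]}")
    extra = set(pheno.line_ids) - set(geno.line_ids)
    if extra:
        raise ValueError(f"phenotyped lines without genotypes: {sorted(extra)[:5]}")
    order = [index[lid] for lid in geno.line_ids]
    return StandardizedPhenotypes(
        line_ids=list(geno.line_ids),
        ybar=pheno.ybar[order],
        sd_used=pheno.sd_used,
        n_i=pheno.n_i[order],
        trait_env=pheno.trait_env,
    )
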