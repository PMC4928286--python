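"""Readers, writers and CpG filtering for methylation matrices.

Beta matrices are delimited text: first column CpG identifiers, header row
specimen identifiers, cells are methylation fractions in [0, 1].  Empty
cells or ``NA`` denote missing measurements; in memory these are NaN and a
boolean mask is exposed.  Covariate tables carry one row per specimen with
numeric or categorical columns (reference level = first declared level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_NA_TOKENS = ["", "NA", "NaN", "nan"]
_RANGE_TOL = 1e-9

__all__ = [
    "BetaMatrix",
    "CovariateTable",
    "CpGAnnotation",
    "load_beta_matrix",
    "write_beta_matrix",
    "load_covariates",
    "load_annotation",
    "read_cpg_list",
    "write_cpg_list",
    "filter_cpgs",
]


def _check_unique(ids, what: str) -> list:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what} identifiers: {sorted(dups)[:5]}")
    return ids


@dataclass
class BetaMatrix:
    """CpG x specimen matrix of methylation fractions with missing-value mask.

    ``values`` is an (m, n) float array with NaN at missing entries; observed
    entries must lie in [0, 1] (a tolerance of 1e-9 absorbs rounding in
    serialized input, after which values are clipped exactly).
    """

    values: np.ndarray
    cpg_ids: list[str]
    specimen_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        self.cpg_ids = _check_unique(self.cpg_ids, "CpG")
        self.specimen_ids = _check_unique(self.specimen_ids, "specimen")
        m, n = self.values.shape
        if len(self.cpg_ids) != m or len(self.specimen_ids) != n:
            raise ValueError("identifier counts do not match matrix dimensions")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (obs.min() < -_RANGE_TOL or obs.max() > 1.0 + _RANGE_TOL):
            bad = obs[(obs < -_RANGE_TOL) | (obs > 1.0 + _RANGE_TOL)]
            raise ValueError(f"beta values outside [0, 1]: e.g. {bad.flat[0]!r}")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (m, n) matrix, True where the measurement is absent."""
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def take_cpgs(self, row_idx: np.ndarray) -> "BetaMatrix":
        return BetaMatrix(
            self.values[row_idx].copy(),
            [self.cpg_ids[i] for i in np.atleast_1d(row_idx)],
            list(self.specimen_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.specimen_ids)


@dataclass
class CovariateTable:
    """Specimen-level phenotype table.

    ``data`` holds one row per specimen; categorical columns are pandas
    Categorical with the reference level first.
    """

    data: pd.DataFrame
    categorical: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = _check_unique(self.data.index, "specimen")
        for col, levels in self.categorical.items():
            if col not in self.data.columns:
                raise KeyError(f"categorical column {col!r} not in table")
            self.data[col] = pd.Categorical(self.data[col].astype(str), categories=[str(l) for l in levels])
            if self.data[col].isna().any():
                raise ValueError(f"column {col!r} has values outside its declared levels")
        for col in self.data.columns:
            if col not in self.categorical:
                if self.data[col].dtype == object:
                    levels = sorted(self.data[col].astype(str).unique())
                    self.categorical[col] = levels
                    self.data[col] = pd.Categorical(self.data[col].astype(str), categories=levels)
                else:
                    self.data[col] = pd.to_numeric(self.data[col])

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.data.index)

    def design_matrix(self, covariates: list[str] | None = None):
        """Intercept-plus-covariate design; categoricals become treatment
        dummies against their reference (first) level.

        Returns (X, column_names, groups) where groups maps each covariate
        to the design-column indices it occupies.
        """
        if covariates is None:
            covariates = list(self.data.columns)
        cols = [np.ones(len(self.data))]
        names = ["(Intercept)"]
        groups: dict[str, list[int]] = {}
        for cov in covariates:
            if cov not in self.data.columns:
                raise KeyError(f"covariate {cov!r} not in table")
            s = self.data[cov]
            idx0 = len(names)
            if isinstance(s.dtype, pd.CategoricalDtype):
                for level in s.cat.categories[1:]:
                    cols.append((s == level).to_numpy(dtype=float))
                    names.append(f"{cov}[{level}]")
            else:
                cols.append(s.to_numpy(dtype=float))
                names.append(cov)
            groups[cov] = list(range(idx0, len(names)))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return X, names, groups


@dataclass
class CpGAnnotation:
    """Per-CpG chromosome label and probe-exclusion flag."""

    cpg_ids: list[str]
    chromosome: np.ndarray
    excluded_flags: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = _check_unique(self.cpg_ids, "CpG")
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.excluded_flags = np.asarray(self.excluded_flags, dtype=bool)
        if not (len(self.cpg_ids) == len(self.chromosome) == len(self.excluded_flags)):
            raise ValueError("annotation fields must have one record per CpG")


def load_beta_matrix(path, delimiter: str = "\t") -> BetaMatrix:
    """Read a CpG x specimen beta matrix from delimited text.

    Empty cells and ``NA`` are treated as missing.  Duplicate identifiers,
    non-numeric cells and values outside [0, 1] (beyond 1e-9) raise
    ``ValueError``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    _check_unique(header, "specimen")  # read_csv silently renames duplicates
    df = pd.read_csv(path, sep=delimiter, index_col=0, na_values=_NA_TOKENS,
                     keep_default_na=False, dtype=str)
    df.columns = header
    try:
        values = df.to_numpy(dtype=object)
        values = np.where(pd.isna(values), np.nan, values).astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    return BetaMatrix(values, list(df.index), list(df.columns))


def write_beta_matrix(beta: BetaMatrix, path, delimiter: str = "\t") -> None:
    """Write a beta matrix; missing entries become empty cells."""
    df = beta.to_frame()
    df.to_csv(path, sep=delimiter, na_rep="", float_format="%.17g",
              index_label="cpg_id")


def load_covariates(path, delimiter: str = "\t",
                    categorical: dict[str, list[str]] | None = None) -> CovariateTable:
    """Read a specimen x covariate table (first column = specimen id).

    ``categorical`` optionally declares levels per column (first level is
    the reference); undeclared object columns become categoricals with
    alphabetically sorted levels.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.map(str)
    return CovariateTable(df, dict(categorical or {}))


def load_annotation(path, delimiter: str = "\t") -> CpGAnnotation:
    """Read annotation with columns cpg_id, chromosome, excluded."""
    df = pd.read_csv(path, sep=delimiter, dtype={"cpg_id": str, "chromosome": str})
    excl = df["excluded"]
    if excl.dtype == object:
        excl = excl.astype(str).str.lower().isin(["true", "1", "yes"])
    return CpGAnnotation(list(df["cpg_id"]), df["chromosome"].to_numpy(),
                         excl.to_numpy(dtype=bool))


def read_cpg_list(path) -> list[str]:
    """Read a plain-text CpG list, one identifier per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_cpg_list(cpg_ids, path) -> None:
    with open(path, "w") as fh:
        for c in cpg_ids:
            fh.write(f"{c}\n")


def filter_cpgs(beta: BetaMatrix, annotation: CpGAnnotation | None = None,
                drop_chromosomes=("Y", "chrY"),
                max_missing_fraction: float = 0.5) -> BetaMatrix:
    """Apply the standard probe filters before deconvolution.

    Removes CpGs on the dropped chromosomes (Y by default; X is left to the
    caller), CpGs flagged as cross-hybridizing/SNP probes, and CpGs whose
    missing fraction strictly exceeds ``max_missing_fraction`` (default: over
    half the specimens).  Row order is otherwise preserved and no value is
    altered; the operation is idempotent.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    m, n = beta.shape
    keep = np.ones(m, dtype=bool)
    if annotation is not None:
        ann_chrom = dict(zip(annotation.cpg_ids, annotation.chromosome))
        ann_excl = dict(zip(annotation.cpg_ids, annotation.excluded_flags))
        missing = [c for c in beta.cpg_ids if c not in ann_chrom]
        if missing:
            raise KeyError(f"annotation missing CpGs present in beta: {missing[:5]}")
        drop = set(str(c) for c in drop_chromosomes)
        for i, c in enumerate(beta.cpg_ids):
            if str(ann_chrom[c]) in drop or ann_excl[c]:
                keep[i] = False
    miss_frac = beta.missing_mask.mean(axis=1)
    keep &= ~(miss_frac > max_missing_fraction)
    return beta.take_cpgs(np.flatnonzero(keep))
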