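"""Data model and I/O for count matrices, annotations, sample metadata and gene sets.

All tabular formats are plain TSV (UTF-8, ``#`` comment lines ignored); gene
sets use the standard GMT layout.  The in-memory containers are thin,
validated wrappers around :class:`pandas.DataFrame` so that every downstream
stage can rely on their invariants (unique identifiers, unit tags, TPM
columns summing to one million).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical biotype vocabulary; anything else is coerced to "other".
BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other")

#: Column order of the annotation table.
ANNOTATION_COLUMNS = ("gene_id", "symbol", "biotype", "length_bp")

#: Column order of the sample-metadata (design) table.
DESIGN_COLUMNS = (
    "sample_id",
    "cohort",
    "stage",
    "cea_status",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
    "split",
)

#: Valid expression units and the token used for missing optional metadata.
UNITS = ("counts", "tpm", "log2tpm")
NA_TOKEN = "NA"

#: Relative tolerance on TPM column sums.
TPM_SUM_RTOL = 1e-9
TPM_TOTAL = 1.0e6


class DataError(ValueError):
    """Raised on malformed or inconsistent input tables."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression matrix tagged with its unit.

    Parameters
    ----------
    values
        DataFrame with gene_ids as index and sample_ids as columns.
    unit
        One of ``counts``, ``tpm``, ``log2tpm``.  ``counts`` requires
        non-negative integers; ``tpm`` requires every column to sum to 1e6
        within relative tolerance 1e-9.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise DataError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene_id(s): {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample_id(s): {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression values must be numeric")
        if arr.size and np.isnan(arr).any():
            raise DataError("expression matrix contains NaN")
        if self.unit in ("counts", "tpm") and arr.size and (arr < 0).any():
            raise DataError(f"negative values not allowed in a {self.unit} matrix")
        if self.unit == "counts" and arr.size:
            if not np.allclose(arr, np.round(arr), rtol=0, atol=0):
                g, s = np.argwhere(arr != np.round(arr))[0]
                raise DataError(
                    f"non-integer count at gene {idx[g]!r}, sample {cols[s]!r}"
                )
        if self.unit == "tpm" and arr.size:
            sums = arr.sum(axis=0)
            bad = ~np.isclose(sums, TPM_TOTAL, rtol=TPM_SUM_RTOL, atol=0)
            if bad.any():
                raise DataError(
                    f"TPM column(s) {list(cols[bad][:5])} do not sum to 1e6 "
                    f"(sums {sums[bad][:5]})"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise DataError(f"gene_id(s) not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[gene_ids], self.unit)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise DataError(f"sample_id(s) not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[sample_ids], self.unit)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style): set name -> frozen set of member gene ids."""

    sets: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets that become empty."""
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = frozenset(members & uni)
            if inter:
                kept[name] = inter
            else:
                logger.warning("gene set %r has no member in the universe; dropped", name)
        return GeneSetCollection(kept)


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.empty:
        raise DataError(f"{path}: no data rows")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV with columns gene_id, symbol, biotype, length_bp.

    Unknown biotypes are coerced to ``other``.  gene_id must be unique and
    length_bp a positive integer (union-exon length in bp).
    """
    df = _read_tsv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing annotation column(s) {missing}")
    df = df[list(ANNOTATION_COLUMNS)].copy()
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise DataError(f"{path}: duplicate gene_id(s): {dups[:5]}")
    unknown = ~df["biotype"].isin(BIOTYPES)
    if unknown.any():
        logger.warning(
            "%d gene(s) with unrecognized biotype coerced to 'other'", int(unknown.sum())
        )
        df.loc[unknown, "biotype"] = "other"
    try:
        df["length_bp"] = df["length_bp"].astype(int)
    except ValueError as exc:
        raise DataError(f"{path}: non-integer length_bp ({exc})") from None
    if (df["length_bp"] < 1).any():
        bad = df.loc[df["length_bp"] < 1, "gene_id"].tolist()
        raise DataError(f"{path}: length_bp < 1 for gene(s) {bad[:5]}")
    return df.reset_index(drop=True)


def strip_versions(annotation: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the annotation with Ensembl-style ID versions removed.

    Versioned IDs ("ENSG00000272196.2") are matched on the full string by
    default everywhere in the package; this helper supports cross-annotation
    reuse when version-stripped matching is wanted.
    """
    out = annotation.copy()
    out["gene_id"] = out["gene_id"].str.replace(r"\.\d+$", "", regex=True)
    if out["gene_id"].duplicated().any():
        raise DataError("version stripping produced duplicate gene_ids")
    return out


def read_counts(
    path: str | Path,
    annotation: pd.DataFrame,
    *,
    match_versions: bool = True,
) -> ExpressionMatrix:
    """Read a gene-level read-count TSV (first column gene_id, header sample_ids).

    Rows whose gene_id is absent from ``annotation`` are dropped with a
    warning.  Duplicate gene_ids or non-integer counts are hard errors.
    """
    df = _read_tsv(path)
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate gene_id(s): {dups[:5]}")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                row = df.index[bad][0]
                raise DataError(
                    f"{path}: non-numeric count at gene {row!r}, sample {col!r}"
                ) from None
        raise
    annot_ids = annotation["gene_id"]
    if not match_versions:
        matrix_ids = values.index.str.replace(r"\.\d+$", "", regex=True)
        values.index = matrix_ids
        annot_ids = annot_ids.str.replace(r"\.\d+$", "", regex=True)
    known = values.index.isin(set(annot_ids))
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.warning(
            "%d gene(s) in %s absent from annotation; dropped (e.g. %s)",
            n_dropped,
            path,
            values.index[~known][:3].tolist(),
        )
    values = values.loc[known]
    if values.empty:
        raise DataError(f"{path}: no gene overlaps the annotation")
    arr = values.to_numpy()
    frac = arr != np.round(arr)
    if frac.any():
        g, s = np.argwhere(frac)[0]
        raise DataError(
            f"{path}: non-integer count at gene {values.index[g]!r}, "
            f"sample {values.columns[s]!r}"
        )
    return ExpressionMatrix(values, "counts")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV into the canonical design table.

    Optional fields use the explicit token ``NA``; they come back as pandas
    NA / NaN.  Event flags are parsed from {0,1,true,false} (case-insensitive).
    """
    df = _read_tsv(path)
    if "sample_id" not in df.columns or "cohort" not in df.columns:
        raise DataError(f"{path}: design table needs sample_id and cohort columns")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"{path}: duplicate sample_id(s): {dups[:5]}")
    out = pd.DataFrame({"sample_id": df["sample_id"], "cohort": df["cohort"]})
    bad = ~out["cohort"].isin(("CRC", "CRA", "healthy"))
    if bad.any():
        raise DataError(
            f"{path}: unknown cohort label(s) {out.loc[bad, 'cohort'].unique().tolist()}"
        )
    for col in ("stage", "cea_status", "split"):
        out[col] = df[col].replace(NA_TOKEN, pd.NA) if col in df.columns else pd.NA
    for col in ("os_time", "dfs_time"):
        if col in df.columns:
            out[col] = pd.to_numeric(df[col].replace(NA_TOKEN, pd.NA), errors="raise")
        else:
            out[col] = np.nan
    for col in ("os_event", "dfs_event"):
        if col in df.columns:
            raw = df[col].replace(NA_TOKEN, pd.NA)
            mapped = raw.str.lower().map(
                {"1": True, "true": True, "0": False, "false": False}
            )
            if (mapped.isna() & raw.notna()).any():
                raise DataError(f"{path}: unparseable boolean in column {col}")
            out[col] = mapped.astype("boolean")
        else:
            out[col] = pd.array([pd.NA] * len(out), dtype="boolean")
    for tcol, ecol in (("os_time", "os_event"), ("dfs_time", "dfs_event")):
        observed = out[ecol].fillna(False).to_numpy(dtype=bool)
        if (observed & out[tcol].isna().to_numpy()).any():
            raise DataError(f"{path}: {ecol}=true with missing {tcol}")
        if (out[tcol].dropna() < 0).any():
            raise DataError(f"{path}: negative {tcol}")
    return out.reset_index(drop=True)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, members; tab-separated)."""
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); need >=3"
                )
            name = fields[0]
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate set {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise DataError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    if not sets:
        raise DataError(f"{path}: no gene sets")
    return GeneSetCollection(sets)


def join_design(
    matrix: ExpressionMatrix, design: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Align a matrix and design table on their shared samples.

    Returns the pair restricted to samples present in both, in matrix column
    order; samples dropped from either side are logged.
    """
    design_ids = set(design["sample_id"])
    shared = [s for s in matrix.sample_ids if s in design_ids]
    if not shared:
        raise DataError("no overlapping samples between matrix and design")
    dropped_matrix = [s for s in matrix.sample_ids if s not in design_ids]
    dropped_design = sorted(design_ids - set(matrix.sample_ids))
    if dropped_matrix:
        logger.warning("samples only in matrix dropped: %s", dropped_matrix[:5])
    if dropped_design:
        logger.warning("samples only in design dropped: %s", dropped_design[:5])
    sub = design.set_index("sample_id").loc[shared].reset_index()
    return matrix.subset_samples(shared), sub


# ---------------------------------------------------------------------------
# writers


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")
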