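"""Readers and writers for every external table the pipeline touches.

All tables are plain TSV/CSV with a header row.  Gene ids and family labels
are opaque strings; column order in files is never semantically meaningful.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .model import (
    AnnotationMap,
    CtTable,
    ExpressionMatrix,
    FamilyDesign,
    FormatError,
    PhenotypeTable,
)

__all__ = [
    "read_phenotype_table",
    "write_phenotype_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "read_ct_table",
    "write_results",
]

_FLOAT_FMT = "%.6g"


def _read_table(path: str | os.PathLike, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_phenotype_table(
    path: str | os.PathLike, design: FamilyDesign | None = None
) -> PhenotypeTable:
    """Read an individual-level phenotype CSV (individual_id, family, traits...).

    Unknown family labels (relative to *design*) are rejected, and
    non-numeric trait values raise a parse error naming the row.
    """
    df = _read_table(path)
    for col in ("individual_id", "family"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    traits = [c for c in df.columns if c not in ("individual_id", "family")]
    for trait in traits:
        coerced = pd.to_numeric(df[trait], errors="coerce")
        bad = df.index[coerced.isna() & df[trait].notna()]
        if len(bad):
            raise FormatError(f"{path}: non-numeric value for trait {trait!r} at row {bad[0]}")
        if coerced.isna().any():
            raise FormatError(f"{path}: missing value for trait {trait!r}")
        df[trait] = coerced
    return PhenotypeTable(data=df, design=design)


def write_phenotype_table(table: PhenotypeTable, path: str | os.PathLike) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_expression_matrix(
    values_path: str | os.PathLike,
    meta_path: str | os.PathLike,
    unit: str = "FPKM",
) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample metadata TSV.

    The values table has gene ids in its first column; the metadata table has
    columns sample_id, family, replicate and must cover every sample column.
    """
    vals = _read_table(values_path, sep="\t")
    gene_col = vals.columns[0]
    vals = vals.set_index(gene_col)
    vals.index = vals.index.astype(str)
    vals.index.name = "gene_id"

    meta = _read_table(meta_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise FormatError(f"{meta_path}: missing required column 'sample_id'")
    meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    vals.columns = vals.columns.astype(str)
    return ExpressionMatrix(values=vals, sample_meta=meta, unit=unit)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    values_path: str | os.PathLike,
    meta_path: str | os.PathLike,
) -> tuple[Path, Path]:
    values_path, meta_path = Path(values_path), Path(meta_path)
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(values_path, sep="\t", float_format=_FLOAT_FMT)
    meta = matrix.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")
    return values_path, meta_path


def read_annotation(path: str | os.PathLike) -> AnnotationMap:
    """Read a gene_id / term_id (/ term_name) TSV into an AnnotationMap."""
    df = _read_table(path, sep="\t")
    for col in ("gene_id", "term_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    gene_to_terms: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"].astype(str), df["term_id"].astype(str)):
        gene_to_terms.setdefault(g, set()).add(t)
    names: dict[str, str] = {}
    if "term_name" in df.columns:
        for t, name in zip(df["term_id"].astype(str), df["term_name"]):
            if pd.notna(name):
                names[t] = str(name)
    return AnnotationMap(gene_to_terms=gene_to_terms, term_names=names)


def read_ct_table(path: str | os.PathLike) -> CtTable:
    """Read a qPCR Ct CSV (gene_id, family, replicate, ct_target, ct_reference)."""
    df = _read_table(path)
    for col in CtTable.REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("ct_target", "ct_reference"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0])
            raise FormatError(f"{path}: non-numeric {col} at row {row}")
        df[col] = coerced
    return CtTable(data=df)


def write_results(report: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a result table as TSV with a deterministic column order.

    Floats are formatted at 6 significant digits.  Empty reports are an
    error: a silent empty file would hide an upstream failure.
    """
    if report is None or len(report) == 0:
        raise ValueError(f"refusing to write empty report to {path}")
    path = Path(path)
    report.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path
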