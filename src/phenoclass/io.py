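"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices are tab-separated (genes in rows by default, header row of
sample ids); IHC tables are comma- or tab-separated with samples in rows; gene
sets use the standard GMT layout; label tables are two-column TSV.  Lines
starting with ``#`` are treated as comments everywhere, which is where
pipeline outputs carry their configuration hash.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneSetCollection,
    IHCTable,
    LabelTable,
    MARKER_PANEL,
    ParseError,
    ValidationError,
)

__all__ = [
    "DEFAULT_MISSING_TOKENS",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ihc_table",
    "write_ihc_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_label_table",
    "write_label_table",
]

#: Tokens interpreted as a missing IHC evaluation.
DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"", "NA", "NaN", "X"})


def _header_fields(path: Path, sep: str) -> list[str]:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return line.rstrip("\n").split(sep)
    return []


def _read_raw_table(path: str | Path, sep: Optional[str]) -> pd.DataFrame:
    """Read a delimited table as strings; first column becomes the index.

    ``sep=None`` sniffs tab vs comma from the header line.  Duplicate header
    fields are preserved verbatim (pandas would otherwise mangle them), so
    callers can apply their own duplicate policy.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    if sep is None:
        header = _header_fields(path, "\t")
        sep = "\t" if len(header) > 1 or "," not in (header[0] if header else "") else ","
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            comment="#",
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        raise ParseError(f"empty file: {path}") from None
    if df.shape[0] == 0 and df.shape[1] == 0:
        raise ParseError(f"empty table: {path}")
    header = _header_fields(path, sep)
    if len(header) == df.shape[1] + 1:
        df.columns = header[1:]  # undo pandas' mangling of duplicate names
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def _to_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    columns = []
    for j in range(df.shape[1]):
        col = df.iloc[:, j]
        name = df.columns[j]
        converted = pd.to_numeric(col, errors="coerce")
        bad = converted.isna() & (col.str.strip() != "")
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(
                f"malformed numeric cell at row {row!r}, column {name!r} in {path}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().argmax()]
            raise ParseError(
                f"empty numeric cell at row {row!r}, column {name!r} in {path}"
            )
        columns.append(converted.rename(name))
    return pd.concat(columns, axis=1)


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes-in-rows",
) -> ExpressionMatrix:
    """Read a log2 expression matrix from TSV.

    Parameters
    ----------
    path:
        Tab-separated file; first column holds row ids, first row column ids.
    orientation:
        ``"genes-in-rows"`` (default) or ``"samples-in-rows"``; the latter is
        transposed after reading so that the result is always genes x samples.

    Duplicate gene ids are collapsed to the row of highest variance (a warning
    is emitted); duplicate sample ids are an error.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _to_numeric(_read_raw_table(path, sep="\t"), path)
    if orientation == "samples-in-rows":
        df = df.T
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValidationError(f"duplicate sample ids in {path}: {dups[:10]}")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        warnings.warn(
            f"duplicate gene ids collapsed by maximum variance: {dups[:10]}",
            stacklevel=2,
        )
        variances = df.var(axis=1, ddof=1).fillna(0.0)
        keep = np.zeros(len(df), dtype=bool)
        for gene in df.index.unique():
            positions = np.flatnonzero(df.index == gene)
            best = positions[int(np.argmax(variances.iloc[positions].to_numpy()))]
            keep[best] = True
        df = df.iloc[keep]
    return ExpressionMatrix(df)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    header_comment: Optional[str] = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")


def read_ihc_table(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    max_intensity: int = 3,
) -> IHCTable:
    """Read a per-sample IHC marker-intensity table (CSV or TSV, sniffed).

    The header row gives marker names; each subsequent row is one sample.
    Listed missing tokens map to NaN; any other cell must be an integer in
    ``0..max_intensity``.  Marker columns outside the canonical panel are
    retained but flagged with a warning.
    """
    raw = _read_raw_table(path, sep=None)
    if raw.shape[1] == 0:
        raise ValidationError(f"IHC table has no marker columns: {path}")
    tokens = {t.upper() for t in missing_tokens}
    cleaned = raw.apply(lambda col: col.str.strip())
    masked = cleaned.mask(cleaned.apply(lambda col: col.str.upper().isin(tokens)))
    numeric = {}
    for col in masked.columns:
        converted = pd.to_numeric(masked[col], errors="coerce")
        bad = converted.isna() & masked[col].notna()
        if bad.any():
            row = masked.index[bad.argmax()]
            raise ValidationError(
                f"non-numeric intensity at sample {row!r}, marker {col!r} in {path}"
            )
        numeric[col] = converted
    df = pd.DataFrame(numeric, index=masked.index)
    unknown = [m for m in df.columns.str.upper() if m not in MARKER_PANEL]
    if unknown:
        warnings.warn(
            f"marker columns outside the canonical panel retained: {unknown}",
            stacklevel=2,
        )
    return IHCTable(df, max_intensity=max_intensity)


def write_ihc_table(
    table: IHCTable,
    path: str | Path,
    header_comment: Optional[str] = None,
    missing_token: str = "NA",
) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = table.values.map(lambda v: missing_token if pd.isna(v) else str(int(v)))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep=sep, index_label="sample_id")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, genes...)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    sets: dict[str, tuple[str, ...]] = {}
    provenance: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line {lineno} has {len(fields)} fields (need >= 3): {path}"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r} at line {lineno}")
            genes = [g for g in genes if g.strip()]
            sets[name] = tuple(dict.fromkeys(genes))
            provenance[name] = desc
    if not sets:
        raise ParseError(f"no gene sets found in {path}")
    return GeneSetCollection(sets, provenance)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_label_table(
    path: str | Path,
    vocabulary: Optional[Iterable[str]] = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> LabelTable:
    """Read a two-column TSV ``sample_id<TAB>label``."""
    raw = _read_raw_table(path, sep="\t")
    if raw.shape[1] != 1:
        raise ParseError(
            f"label table must have exactly two columns (sample_id, label): {path}"
        )
    col = raw.columns[0]
    tokens = {t.upper() for t in missing_tokens}
    labels = raw[col].str.strip()
    labels = labels.mask(labels.str.upper().isin(tokens))
    if vocabulary is None:
        vocabulary = tuple(dict.fromkeys(labels.dropna()))
    return LabelTable(labels, tuple(vocabulary))


def write_label_table(
    table: LabelTable,
    path: str | Path,
    header_comment: Optional[str] = None,
    label_name: str = "label",
    missing_token: str = "NA",
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = table.labels.fillna(missing_token)
        out.rename(label_name).to_csv(fh, sep="\t", index_label="sample_id")
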