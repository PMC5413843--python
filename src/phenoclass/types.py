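"""Core tabular containers shared by all pipeline stages.

The pipeline moves four kinds of data around: a log2 expression matrix
(genes x samples), a table of ordinal immunohistochemistry (IHC) labelling
intensities (samples x markers), named gene sets, and per-sample categorical
labels (consensus clusters, tumour-cell phenotypes, deconstructed classes).
Each container is a thin, validated wrapper around a pandas object so that
every stage can rely on the same invariants: unique non-empty identifiers,
finite values, ordinal intensities within the declared scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenoclassError",
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "IHCTable",
    "GeneSetCollection",
    "LabelTable",
    "PHENOTYPES",
    "UNCLASSIFIED",
    "DECONSTRUCTED_CLASSES",
    "CONTEXTS",
    "MARKER_PANEL",
]


class PhenoclassError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PhenoclassError):
    """Input violates a declared invariant (ids, ranges, alignment)."""


class ParseError(PhenoclassError):
    """A file could not be parsed into the expected tabular structure."""


#: Tumour-cell phenotype vocabulary.  URO = urothelial-like, GU = genomically
#: unstable, BASAL_SCC = basal/squamous-cell-carcinoma-like, MES_LIKE =
#: mesenchymal-like, SCNE_LIKE = small-cell/neuroendocrine-like.
PHENOTYPES: tuple[str, ...] = ("URO", "GU", "BASAL_SCC", "MES_LIKE", "SCNE_LIKE")

UNCLASSIFIED = "UNCLASSIFIED"

#: Deconstructed class vocabulary (cluster x phenotype combinations regrouped).
DECONSTRUCTED_CLASSES: tuple[str, ...] = ("Uro", "GU", "BasalSCC", "MesLike", "ScNELike")

#: Expression-context (consensus cluster) vocabulary used by the synthetic
#: cohort: the tumour-cell phenotype plus the infiltration/proliferation
#: context jointly determine which global expression cluster a sample joins.
CONTEXTS: tuple[str, ...] = (
    "Uro",
    "GU",
    "EpiInf",
    "SCCL_MesInf",
    "SCCL_UroB",
    "ScNE",
)

#: The IHC marker panel evaluated on tumour cells.
MARKER_PANEL: tuple[str, ...] = (
    "CCNB1",
    "CCND1",
    "CDH1",
    "CDH3",
    "CDKN2A",
    "CHGA",
    "E2F3",
    "EPCAM",
    "FGFR3",
    "FOXA1",
    "GATA3",
    "KRT5",
    "KRT14",
    "KRT20",
    "NCAM1",
    "PPARG",
    "RB1",
    "RXRA",
    "SYP",
    "TP63",
    "TUBB2B",
    "UPK3",
    "VIM",
    "ZEB2",
)


def _check_unique_ids(ids: pd.Index, axis: str) -> None:
    if len(ids) == 0:
        raise ValidationError(f"{axis} ids are empty")
    as_str = ids.astype(str)
    if (as_str.str.len() == 0).any():
        raise ValidationError(f"empty {axis} id found")
    if as_str.duplicated().any():
        dups = sorted(set(as_str[as_str.duplicated()]))
        raise ValidationError(f"duplicate {axis} ids: {dups[:10]}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 gene-expression values, genes in rows, samples in columns."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("ExpressionMatrix.values must be a DataFrame")
        _check_unique_ids(df.index, "gene")
        _check_unique_ids(df.columns, "sample")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        object.__setattr__(self, "values", df.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)])

    def select_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values[list(samples)])

    def gene(self, gene_id: str) -> pd.Series:
        """Per-sample log2 values of one gene."""
        if gene_id not in self.values.index:
            raise ValidationError(f"gene {gene_id!r} not in matrix")
        return self.values.loc[gene_id]


@dataclass(frozen=True)
class IHCTable:
    """Ordinal tumour-cell labelling intensities, samples in rows.

    Intensities live on the pathology convention 0 (negative) .. 3 (strong);
    missing evaluations are NaN.  The scale maximum is configurable.
    """

    values: pd.DataFrame
    max_intensity: int = 3

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("IHCTable.values must be a DataFrame")
        if df.shape[1] == 0:
            raise ValidationError("IHC table has no marker columns")
        _check_unique_ids(df.index, "sample")
        _check_unique_ids(df.columns, "marker")
        df = df.rename(columns=str.upper)
        if df.columns.duplicated().any():
            raise ValidationError("marker names collide after case normalisation")
        df = df.astype(float)
        arr = df.to_numpy()
        present = ~np.isnan(arr)
        vals = arr[present]
        if ((vals < 0) | (vals > self.max_intensity)).any() or (vals != np.round(vals)).any():
            bad = np.argwhere(present & ((arr < 0) | (arr > self.max_intensity) | (arr != np.round(arr))))[0]
            raise ValidationError(
                f"intensity outside ordinal 0..{self.max_intensity} at sample "
                f"{df.index[bad[0]]!r}, marker {df.columns[bad[1]]!r}"
            )
        object.__setattr__(self, "values", df)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def marker_names(self) -> list[str]:
        return [str(m) for m in self.values.columns]

    def marker(self, name: str) -> pd.Series:
        name = name.upper()
        if name not in self.values.columns:
            raise ValidationError(f"marker {name!r} not in IHC table")
        return self.values[name]

    def row(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.index:
            raise ValidationError(f"sample {sample_id!r} not in IHC table")
        return self.values.loc[sample_id]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (signature name -> member genes) with provenance notes."""

    sets: Mapping[str, tuple[str, ...]]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sets) == 0:
            raise ValidationError("gene-set collection is empty")
        clean: dict[str, tuple[str, ...]] = {}
        for name, genes in self.sets.items():
            if not name:
                raise ValidationError("empty gene-set name")
            deduped = tuple(dict.fromkeys(str(g) for g in genes))
            if len(deduped) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[str(name)] = deduped
        object.__setattr__(self, "sets", clean)
        object.__setattr__(self, "provenance", dict(self.provenance))

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class LabelTable:
    """Per-sample categorical labels drawn from a declared vocabulary.

    Missing labels are NaN.  ``labels`` is a Series indexed by sample id.
    """

    labels: pd.Series
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        s = self.labels
        if not isinstance(s, pd.Series):
            raise ValidationError("LabelTable.labels must be a Series")
        _check_unique_ids(s.index, "sample")
        vocab = tuple(str(v) for v in self.vocabulary)
        if len(set(vocab)) != len(vocab):
            raise ValidationError("label vocabulary contains duplicates")
        present = s.dropna()
        bad = sorted(set(present) - set(vocab))
        if bad:
            raise ValidationError(f"labels outside vocabulary {vocab}: {bad[:10]}")
        object.__setattr__(self, "labels", s.astype(object))
        object.__setattr__(self, "vocabulary", vocab)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.labels.index]

    def align_with(self, other: "LabelTable") -> tuple[pd.Series, pd.Series]:
        """Return the two label series over the shared samples.

        Raises if the sample universes differ (symmetric difference listed).
        """
        a, b = set(self.labels.index), set(other.labels.index)
        if a != b:
            diff = sorted(a.symmetric_difference(b))
            raise ValidationError(
                f"sample universes differ; symmetric difference: {diff[:20]}"
            )
        order = sorted(a)
        return self.labels.loc[order], other.labels.loc[order]

    def counts(self) -> pd.Series:
        return self.labels.value_counts(dropna=False)
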