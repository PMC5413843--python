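"""Formula-defined marker scores.

Two composite scores summarise the tumour-cell phenotype axes of urothelial
carcinoma.  The genomic circuit score,

    FGFR3 + CCND1 + RB1 - E2F3,

is high in urothelial-like (Uro) tumours (FGFR3/CCND1 expression with
retained RB1) and low in genomically unstable (GU) tumours (RB1 loss, E2F3
gain).  The basal/squamous score,

    FOXA1 + GATA3 - KRT5 - KRT14,

is low in basal/SCC-like tumours (basal keratins up, urothelial
differentiation factors down).  Both are computed either from log2 mRNA
values or from ordinal IHC labelling intensities; the formula is identical
at both levels.  Note that published colour legends occasionally render the
basal/squamous axis with the opposite orientation; this module keeps the
methods formula (basal/SCC-like = low) and never flips signs.

Also here: per-sample mean expression of a gene signature, percentile
mapping of a score vector to [0, 1], and the variance filter that restricts
clustering to the most variable genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import ExpressionMatrix, IHCTable, ValidationError

__all__ = [
    "ScoreVector",
    "signature_score",
    "circuit_score",
    "basq_score",
    "circuit_score_from_expr",
    "circuit_score_from_ihc",
    "basq_score_from_expr",
    "basq_score_from_ihc",
    "percentile_map",
    "variance_filter",
]

CIRCUIT_MARKERS = ("FGFR3", "CCND1", "RB1", "E2F3")
BASQ_MARKERS = ("FOXA1", "GATA3", "KRT5", "KRT14")


@dataclass(frozen=True)
class ScoreVector:
    """One score value (or NaN) per sample."""

    values: pd.Series
    score_name: str
    level: str  # "mRNA" or "IHC"

    def __post_init__(self) -> None:
        if self.level not in ("mRNA", "IHC"):
            raise ValidationError(f"level must be 'mRNA' or 'IHC', got {self.level!r}")
        s = self.values.astype(float)
        arr = s.to_numpy()
        if np.isinf(arr).any():
            raise ValidationError(f"infinite value in score {self.score_name!r}")
        object.__setattr__(self, "values", s)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]


def signature_score(
    expr: ExpressionMatrix,
    genes: Iterable[str],
    score_name: str = "signature",
) -> ScoreVector:
    """Per-sample arithmetic mean of log2 values over the signature genes.

    Genes absent from the matrix are ignored with a warning; if no signature
    gene is present an error lists the missing genes.
    """
    genes = [str(g).upper() for g in genes]
    index_upper = {str(g).upper(): g for g in expr.values.index}
    present = [index_upper[g] for g in genes if g in index_upper]
    absent = [g for g in genes if g not in index_upper]
    if not present:
        raise ValidationError(
            f"no gene of signature {score_name!r} present in matrix; missing: {absent}"
        )
    if absent:
        warnings.warn(
            f"signature {score_name!r}: {len(absent)} gene(s) absent, ignored: "
            f"{absent[:10]}",
            stacklevel=2,
        )
    means = expr.values.loc[present].mean(axis=0)
    return ScoreVector(means, score_name=score_name, level="mRNA")


def _aligned(components: dict[str, pd.Series]) -> dict[str, pd.Series]:
    sets = {name: set(s.index) for name, s in components.items()}
    first = next(iter(sets.values()))
    for name, ids in sets.items():
        if ids != first:
            raise ValidationError(
                f"component {name!r} is not aligned on the same samples; "
                f"symmetric difference: {sorted(first ^ ids)[:10]}"
            )
    order = list(next(iter(components.values())).index)
    return {name: s.loc[order].astype(float) for name, s in components.items()}


def circuit_score(
    fgfr3: pd.Series,
    ccnd1: pd.Series,
    rb1: pd.Series,
    e2f3: pd.Series,
    level: str = "mRNA",
) -> ScoreVector:
    """Genomic circuit score FGFR3 + CCND1 + RB1 - E2F3 (elementwise).

    Any missing component makes the composite missing for that sample; high
    values indicate a Uro phenotype, low values a GU phenotype.
    """
    c = _aligned({"FGFR3": fgfr3, "CCND1": ccnd1, "RB1": rb1, "E2F3": e2f3})
    vals = c["FGFR3"] + c["CCND1"] + c["RB1"] - c["E2F3"]
    return ScoreVector(vals, score_name="circuit", level=level)


def basq_score(
    foxa1: pd.Series,
    gata3: pd.Series,
    krt5: pd.Series,
    krt14: pd.Series,
    level: str = "mRNA",
) -> ScoreVector:
    """Basal/squamous score FOXA1 + GATA3 - KRT5 - KRT14 (elementwise).

    Low values indicate a basal/SCC-like direction (methods-formula
    convention).  Missing components propagate.
    """
    c = _aligned({"FOXA1": foxa1, "GATA3": gata3, "KRT5": krt5, "KRT14": krt14})
    vals = c["FOXA1"] + c["GATA3"] - c["KRT5"] - c["KRT14"]
    return ScoreVector(vals, score_name="basq", level=level)


def _zscale(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValidationError(f"cannot z-scale constant gene {s.name!r}")
    return (s - s.mean()) / sd


def circuit_score_from_expr(
    expr: ExpressionMatrix, standardize: bool = False
) -> ScoreVector:
    rows = {g: expr.gene(g) for g in CIRCUIT_MARKERS}
    if standardize:
        rows = {g: _zscale(s) for g, s in rows.items()}
    return circuit_score(rows["FGFR3"], rows["CCND1"], rows["RB1"], rows["E2F3"], "mRNA")


def circuit_score_from_ihc(table: IHCTable) -> ScoreVector:
    return circuit_score(
        table.marker("FGFR3"),
        table.marker("CCND1"),
        table.marker("RB1"),
        table.marker("E2F3"),
        level="IHC",
    )


def basq_score_from_expr(
    expr: ExpressionMatrix, standardize: bool = False
) -> ScoreVector:
    rows = {g: expr.gene(g) for g in BASQ_MARKERS}
    if standardize:
        rows = {g: _zscale(s) for g, s in rows.items()}
    return basq_score(rows["FOXA1"], rows["GATA3"], rows["KRT5"], rows["KRT14"], "mRNA")


def basq_score_from_ihc(table: IHCTable) -> ScoreVector:
    return basq_score(
        table.marker("FOXA1"),
        table.marker("GATA3"),
        table.marker("KRT5"),
        table.marker("KRT14"),
        level="IHC",
    )


def percentile_map(scores: ScoreVector) -> ScoreVector:
    """Map each value to its fractional rank (rank-1)/(n-1) in [0, 1].

    Ties receive the average rank; missing values are preserved; at least two
    non-missing values are required.
    """
    vals = scores.values.to_numpy(dtype=float)
    mask = ~np.isnan(vals)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(f"all values of {scores.score_name!r} are missing")
    if n < 2:
        raise ValidationError(
            f"percentile mapping needs >= 2 non-missing values, got {n}"
        )
    out = np.full_like(vals, np.nan)
    ranks = rankdata(vals[mask], method="average")
    out[mask] = (ranks - 1.0) / (n - 1.0)
    return ScoreVector(
        pd.Series(out, index=scores.values.index),
        score_name=f"{scores.score_name}_pctl",
        level=scores.level,
    )


def variance_filter(expr: ExpressionMatrix, fraction: float) -> ExpressionMatrix:
    """Keep the ``ceil(fraction * n_genes)`` genes of highest variance.

    Variance is the per-gene sample variance (ddof=1); ties are broken by
    gene-id lexicographic order.  The sample set is unchanged and retained
    genes keep their input order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    n_keep = math.ceil(fraction * expr.n_genes)
    variances = expr.values.var(axis=1, ddof=1).fillna(0.0)
    order = sorted(
        expr.values.index, key=lambda g: (-variances.loc[g], str(g))
    )
    keep = set(order[:n_keep])
    kept_in_input_order = [g for g in expr.values.index if g in keep]
    return ExpressionMatrix(expr.values.loc[kept_in_input_order])
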