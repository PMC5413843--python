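"""Deconstruction of (cluster x phenotype) combinations and concordance.

Global expression clusters mix tumour-cell phenotype with infiltration
context: a cluster can hold tumours of more than one phenotype, and one
phenotype can spread over several clusters.  The deconstruction step
regroups (cluster, phenotype) combinations into the final classes -- e.g.
Uro-phenotype cases of the Uro, GU and Epi-Inf clusters all count as the
class Uro, while GU-phenotype cases of the GU and Sc/NE clusters form the
class GU, and basal/SCC-like cases are combined regardless of cluster.
Concordance between phenotype calls and the deconstructed classes is then
quantified by a multiclass confusion summary (overall accuracy, per-class
sensitivity and one-vs-rest specificity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    DECONSTRUCTED_CLASSES,
    LabelTable,
    UNCLASSIFIED,
    ValidationError,
)

__all__ = [
    "DeconstructionMap",
    "ConfusionSummary",
    "PHENOTYPE_TO_CLASS",
    "deconstruct",
    "confusion_summary",
    "crosstab_report",
]

#: Phenotype vocabulary -> deconstructed class vocabulary.
PHENOTYPE_TO_CLASS: dict[str, str] = {
    "URO": "Uro",
    "GU": "GU",
    "BASAL_SCC": "BasalSCC",
    "MES_LIKE": "MesLike",
    "SCNE_LIKE": "ScNELike",
}

#: Wildcard cluster key.
ANY = "*"


@dataclass(frozen=True)
class DeconstructionMap:
    """Ordered rules mapping (cluster, phenotype) -> deconstructed class.

    Exact (cluster, phenotype) keys take precedence over wildcard
    ``("*", phenotype)`` keys; unmapped combinations yield missing.
    """

    rules: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], str] = {}
        for (cluster, phenotype), cls in self.rules.items():
            if cls not in DECONSTRUCTED_CLASSES:
                raise ValidationError(
                    f"unknown deconstructed class {cls!r} for ({cluster}, {phenotype})"
                )
            clean[(str(cluster), str(phenotype))] = cls
        object.__setattr__(self, "rules", clean)

    def lookup(self, cluster: str, phenotype: str) -> Optional[str]:
        if phenotype == UNCLASSIFIED or pd.isna(phenotype) or pd.isna(cluster):
            return None
        exact = self.rules.get((str(cluster), str(phenotype)))
        if exact is not None:
            return exact
        return self.rules.get((ANY, str(phenotype)))

    @classmethod
    def default(cls) -> "DeconstructionMap":
        """The published regrouping over the six-cluster, five-phenotype grid.

        Uro-phenotype cases of the Uro, GU, Epi-Inf and SCCL/UroB clusters
        form one Uro class; GU-phenotype cases of the GU, Epi-Inf and Sc/NE
        clusters form one GU class; basal/SCC-like cases are combined across
        all clusters; Mes-like and Sc/NE-like classes take their members
        from the phenotype call within their home clusters.
        """
        rules: dict[tuple[str, str], str] = {
            ("Uro", "URO"): "Uro",
            ("GU", "URO"): "Uro",
            ("EpiInf", "URO"): "Uro",
            ("SCCL_UroB", "URO"): "Uro",
            ("GU", "GU"): "GU",
            ("EpiInf", "GU"): "GU",
            ("ScNE", "GU"): "GU",
            (ANY, "BASAL_SCC"): "BasalSCC",
            ("SCCL_MesInf", "MES_LIKE"): "MesLike",
            ("ScNE", "SCNE_LIKE"): "ScNELike",
        }
        return cls(rules)


def deconstruct(
    clusters: LabelTable,
    phenotypes: LabelTable,
    dmap: Optional[DeconstructionMap] = None,
) -> LabelTable:
    """Per-sample deconstructed class from cluster and phenotype labels.

    Both tables must cover the same sample universe (the symmetric
    difference is listed otherwise).  UNCLASSIFIED phenotypes and unmapped
    combinations propagate to missing.
    """
    dmap = dmap or DeconstructionMap.default()
    cl, ph = clusters.align_with(phenotypes)
    out = {
        sample: dmap.lookup(cl.loc[sample], ph.loc[sample])
        for sample in cl.index
    }
    series = pd.Series(out, name="deconstructed", dtype=object)
    return LabelTable(series, vocabulary=DECONSTRUCTED_CLASSES)


@dataclass(frozen=True)
class ConfusionSummary:
    """Cross-tabulation of reference vs predicted classes with metrics."""

    counts: pd.DataFrame  # reference rows x predicted columns
    vocabulary: tuple[str, ...]
    overall_accuracy: float
    sensitivity: Mapping[str, float]
    specificity: Mapping[str, float]
    n_classified: int
    n_unclassified: int

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "sensitivity": dict(self.sensitivity),
            "specificity": dict(self.specificity),
            "n_classified": self.n_classified,
            "n_unclassified": self.n_unclassified,
            "counts": {
                ref: {pred: int(self.counts.loc[ref, pred]) for pred in self.counts.columns}
                for ref in self.counts.index
            },
        }


def confusion_summary(
    reference: LabelTable,
    predicted: LabelTable,
    exclude_missing: bool = True,
    unclassified_as_error: bool = False,
) -> ConfusionSummary:
    """Confusion counts, accuracy and per-class sensitivity/specificity.

    With ``exclude_missing`` (default) only samples carrying both a reference
    and a predicted class enter the metrics; with ``unclassified_as_error``
    samples whose prediction is missing/UNCLASSIFIED count against accuracy
    and sensitivity instead of being dropped.
    """
    ref, pred = reference.align_with(predicted)
    ref = ref.replace(UNCLASSIFIED, np.nan)
    pred_m = pred.replace(UNCLASSIFIED, np.nan)
    has_ref = ref.notna()
    if not has_ref.any():
        raise ValidationError("no sample carries a reference class")
    both = has_ref & pred_m.notna()
    if not both.any():
        raise ValidationError("empty intersection of classified samples")
    n_unclassified = int((has_ref & ~pred_m.notna()).sum())
    vocab = tuple(
        sorted(set(ref.dropna()) | set(pred_m.dropna()))
    )
    if unclassified_as_error:
        eligible = has_ref
        denom = int(eligible.sum())
    else:
        eligible = both
        denom = int(both.sum())
    counts = pd.crosstab(ref[both], pred_m[both]).reindex(
        index=vocab, columns=vocab, fill_value=0
    )
    correct = int(sum(counts.loc[c, c] for c in vocab))
    accuracy = correct / denom
    sensitivity: dict[str, float] = {}
    specificity: dict[str, float] = {}
    for c in vocab:
        ref_is_c = eligible & (ref == c)
        tp = int((ref_is_c & (pred_m == c)).sum())
        fn = int(ref_is_c.sum()) - tp
        not_c = eligible & (ref != c) & ref.notna()
        fp = int((not_c & (pred_m == c)).sum())
        tn = int(not_c.sum()) - fp
        sensitivity[c] = tp / (tp + fn) if (tp + fn) else float("nan")
        specificity[c] = tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionSummary(
        counts=counts,
        vocabulary=vocab,
        overall_accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        n_classified=int(both.sum()),
        n_unclassified=n_unclassified,
    )


def crosstab_report(
    clusters: LabelTable,
    phenotypes: LabelTable,
) -> pd.DataFrame:
    """Per-cluster phenotype composition (counts, UNCLASSIFIED included)."""
    cl, ph = clusters.align_with(phenotypes)
    cl = cl.fillna("MISSING")
    ph = ph.fillna(UNCLASSIFIED)
    table = pd.crosstab(cl, ph)
    table.index.name = "cluster"
    table.columns.name = "phenotype"
    return table
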