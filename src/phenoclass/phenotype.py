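"""Rule-based tumour-cell phenotype calling from IHC marker intensities.

A sample is assigned one of five tumour-cell phenotypes from its ordinal
(0-3) tumour-cell labelling intensities, or left unclassified.  The rules
are evaluated in a fixed precedence order; the two phenotypes defined partly
by marker *absence* (small-cell/neuroendocrine-like and mesenchymal-like)
come first so they are not shadowed by the urothelial branch:

1. SCNE_LIKE  -- >= 2 of {TUBB2B, CHGA, SYP, NCAM1} positive and GATA3
                 negative.
2. MES_LIKE   -- VIM and ZEB2 positive in tumour cells with the epithelial
                 markers CDH1, EPCAM, CDH3 and the basal keratin KRT5 all
                 negative (an EMT-like profile).
3. BASAL_SCC  -- KRT5 positive with FOXA1 and GATA3 negative (KRT14
                 positivity is supportive, not required).
4. URO / GU   -- among urothelial-differentiation-positive samples (GATA3 or
                 FOXA1 positive), the sign of the IHC genomic circuit score
                 FGFR3 + CCND1 + RB1 - E2F3 decides: >= cutoff (default 0)
                 is URO, < cutoff is GU.
5. otherwise UNCLASSIFIED.

Marker positivity is three-valued (positive / negative / missing) and rules
combine states with Kleene logic.  Evaluation is conservative about missing
data: if a rule neither clearly fires nor clearly fails because a defining
marker is missing, the sample is left UNCLASSIFIED rather than allowed to
fall through to a lower-precedence rule -- cases with missing data for the
defining markers are not classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import IHCTable, LabelTable, PHENOTYPES, UNCLASSIFIED, ValidationError

__all__ = [
    "RuleParams",
    "PhenotypeCall",
    "CohortClassification",
    "binarize_marker",
    "classify_sample",
    "classify_cohort",
]

logger = logging.getLogger(__name__)

#: Markers binarised at intensity >= 1: lineage markers whose faint but real
#: tumour-cell staining is already informative.
LINEAGE_MARKERS = ("KRT5", "KRT14", "VIM", "ZEB2", "TUBB2B", "CHGA", "SYP", "NCAM1")

#: Markers binarised at intensity >= 2: graded markers where weak staining is
#: common background (includes the abundance-graded epithelial adhesion
#: markers used as negativity requirements in the mesenchymal rule).
GRADED_MARKERS = (
    "FGFR3",
    "CCND1",
    "RB1",
    "E2F3",
    "CDKN2A",
    "GATA3",
    "FOXA1",
    "CDH1",
    "EPCAM",
    "CDH3",
)

NE_MARKERS = ("TUBB2B", "CHGA", "SYP", "NCAM1")
CIRCUIT_MARKERS = ("FGFR3", "CCND1", "RB1", "E2F3")


def _default_thresholds() -> dict[str, int]:
    th = {m: 1 for m in LINEAGE_MARKERS}
    th.update({m: 2 for m in GRADED_MARKERS})
    return th


@dataclass(frozen=True)
class RuleParams:
    """Tunable thresholds of the phenotype rule set.

    ``thresholds`` maps marker name -> minimal intensity counted as positive;
    ``circuit_cutoff`` separates URO (>= cutoff) from GU (< cutoff) on the
    IHC circuit score, which ranges over -3..9 on the 0-3 ordinal scale;
    ``scne_min_positive`` is the minimal number of positive neuroendocrine
    markers required by the SCNE_LIKE rule.
    """

    thresholds: dict[str, int] = field(default_factory=_default_thresholds)
    circuit_cutoff: float = 0.0
    scne_min_positive: int = 2
    max_intensity: int = 3

    def threshold(self, marker: str) -> int:
        return self.thresholds.get(marker.upper(), 1)


@dataclass(frozen=True)
class PhenotypeCall:
    """The phenotype assigned to one sample plus the evidence behind it."""

    sample_id: str
    phenotype: str
    evidence: dict
    rule_fired: Optional[str]


@dataclass(frozen=True)
class CohortClassification:
    labels: LabelTable
    calls: tuple[PhenotypeCall, ...]
    errors: tuple[tuple[str, str], ...] = ()


# --- three-valued (Kleene) logic: True / False / None (= unknown) ----------

def _k_and(*vals):
    if any(v is False for v in vals):
        return False
    if any(v is None for v in vals):
        return None
    return True


def _k_or(*vals):
    if any(v is True for v in vals):
        return True
    if any(v is None for v in vals):
        return None
    return False


def _k_not(v):
    return None if v is None else (not v)


def binarize_marker(intensity: float, threshold: int) -> Optional[bool]:
    """Positive iff intensity >= threshold; missing (NaN) propagates as None."""
    if not 1 <= threshold <= 3:
        raise ValidationError(f"threshold must be in 1..3, got {threshold}")
    if intensity is None or (isinstance(intensity, float) and np.isnan(intensity)):
        return None
    return bool(intensity >= threshold)


def _binarize_record(record: pd.Series, params: RuleParams) -> dict[str, Optional[bool]]:
    out: dict[str, Optional[bool]] = {}
    for marker, value in record.items():
        m = str(marker).upper()
        out[m] = binarize_marker(
            float(value) if value is not None else np.nan, params.threshold(m)
        )
    return out


def _rule_scne(b: dict, params: RuleParams):
    """>= scne_min_positive of the NE markers positive and GATA3 negative."""
    states = [b.get(m) for m in NE_MARKERS]
    n_pos = sum(1 for s in states if s is True)
    n_unknown = sum(1 for s in states if s is None)
    if n_pos >= params.scne_min_positive:
        count_ok = True
    elif n_pos + n_unknown < params.scne_min_positive:
        count_ok = False
    else:
        count_ok = None
    return _k_and(count_ok, _k_not(b.get("GATA3")))


def _rule_mes(b: dict, params: RuleParams):
    return _k_and(
        b.get("VIM"),
        b.get("ZEB2"),
        _k_not(b.get("CDH1")),
        _k_not(b.get("EPCAM")),
        _k_not(b.get("CDH3")),
        _k_not(b.get("KRT5")),
    )


def _rule_basal(b: dict, params: RuleParams):
    return _k_and(b.get("KRT5"), _k_not(b.get("FOXA1")), _k_not(b.get("GATA3")))


def _urodiff_gate(b: dict, params: RuleParams):
    return _k_or(b.get("GATA3"), b.get("FOXA1"))


_RULES = (
    ("SCNE_LIKE", _rule_scne),
    ("MES_LIKE", _rule_mes),
    ("BASAL_SCC", _rule_basal),
)


def classify_sample(
    record: pd.Series,
    params: Optional[RuleParams] = None,
    sample_id: Optional[str] = None,
) -> PhenotypeCall:
    """Assign a tumour-cell phenotype to one IHC record (marker -> intensity).

    Raises if the record contains no recognised marker.  Returns a
    :class:`PhenotypeCall` whose ``evidence`` holds the binarised defining
    markers, the IHC circuit score when computed, and the state of each rule.
    """
    params = params or RuleParams()
    if sample_id is None:
        sample_id = str(record.name) if record.name is not None else "<sample>"
    record = record.copy()
    record.index = [str(m).upper() for m in record.index]
    known = set(LINEAGE_MARKERS) | set(GRADED_MARKERS)
    recognised = [str(m).upper() for m in record.index if str(m).upper() in known]
    if not recognised:
        raise ValidationError(
            f"record {sample_id!r} contains no recognised defining marker"
        )
    b = _binarize_record(record, params)
    evidence: dict = {
        "binarized": {
            m: {True: "positive", False: "negative", None: "missing"}[b[m]]
            for m in sorted(b)
        },
        "rules": {},
        "circuit_score_ihc": None,
    }

    for name, rule in _RULES:
        state = rule(b, params)
        evidence["rules"][name] = {True: "fired", False: "false", None: "unknown"}[
            True if state is True else state
        ]
        if state is True:
            return PhenotypeCall(sample_id, name, evidence, rule_fired=name)
        if state is None:
            # defining marker missing and the rule cannot be decided
            return PhenotypeCall(sample_id, UNCLASSIFIED, evidence, rule_fired=None)

    gate = _urodiff_gate(b, params)
    if gate is True:
        intensities = [record.get(m, np.nan) for m in CIRCUIT_MARKERS]
        intensities = [np.nan if v is None else float(v) for v in intensities]
        if any(np.isnan(v) for v in intensities):
            evidence["rules"]["URO_GU"] = "unknown"
            return PhenotypeCall(sample_id, UNCLASSIFIED, evidence, rule_fired=None)
        score = intensities[0] + intensities[1] + intensities[2] - intensities[3]
        evidence["circuit_score_ihc"] = score
        if score >= params.circuit_cutoff:
            evidence["rules"]["URO_GU"] = "fired:URO"
            return PhenotypeCall(sample_id, "URO", evidence, rule_fired="URO")
        evidence["rules"]["URO_GU"] = "fired:GU"
        return PhenotypeCall(sample_id, "GU", evidence, rule_fired="GU")
    if gate is None:
        evidence["rules"]["URO_GU"] = "unknown"
        return PhenotypeCall(sample_id, UNCLASSIFIED, evidence, rule_fired=None)
    evidence["rules"]["URO_GU"] = "false"
    return PhenotypeCall(sample_id, UNCLASSIFIED, evidence, rule_fired=None)


def classify_cohort(
    table: IHCTable,
    params: Optional[RuleParams] = None,
) -> CohortClassification:
    """Classify every sample of an IHC table; per-sample errors are collected.

    Samples that raise (e.g. no recognised marker) are recorded in ``errors``
    and assigned UNCLASSIFIED in the label table, so exactly one call exists
    per sample.
    """
    params = params or RuleParams()
    if len(table.sample_ids) == 0:
        raise ValidationError("IHC table is empty")
    calls: list[PhenotypeCall] = []
    errors: list[tuple[str, str]] = []
    labels = {}
    for sample_id in table.sample_ids:
        record = table.values.loc[sample_id]
        try:
            call = classify_sample(record, params, sample_id=sample_id)
        except ValidationError as exc:
            errors.append((sample_id, str(exc)))
            call = PhenotypeCall(sample_id, UNCLASSIFIED, {"error": str(exc)}, None)
        calls.append(call)
        labels[sample_id] = call.phenotype
    series = pd.Series(labels, name="phenotype").loc[table.sample_ids]
    label_table = LabelTable(series, vocabulary=PHENOTYPES + (UNCLASSIFIED,))
    counts = series.value_counts().to_dict()
    logger.info("phenotype calls: %s", counts)
    return CohortClassification(label_table, tuple(calls), tuple(errors))
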