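"""Synthetic tumour/stroma admixture cohorts with known ground truth.

The generator emulates the situation the pipeline is built to analyse: each
sample has a latent *tumour-cell phenotype* (URO, GU, BASAL_SCC, MES_LIKE,
SCNE_LIKE), a tumour purity fraction p, and context covariates -- stromal
(ECM) infiltration, T-cell infiltration, proliferation, and a 6p22-amplicon
indicator.  Bulk expression is the purity-weighted mixture

    bulk_g = p * tumour_g + (1 - p) * stroma_g + N(0, sigma),

where the tumour component is the phenotype's mean marker/signature profile
plus the proliferation amplitude on late-cell-cycle genes and the amplicon
boost on the 6p22 block, and the stromal component carries the ECM and
T-cell amplitudes (stromal cells also express VIM/ZEB2 constitutively).
IHC intensities are discretised from the *tumour component only*, so the
two views can disagree exactly the way bulk and tumour-cell measurements
disagree in tissue: bulk VIM rises in any low-purity sample, but IHC VIM is
positive only when the tumour cells themselves are mesenchymal.

Each sample also carries a latent *context* label -- the expression cluster
it is expected to join.  Contexts are drawn conditionally on phenotype and
plant the convergence/divergence phenomenon:

* a large share of URO-phenotype samples receives the GU-like context
  (high proliferation, moderate infiltration) and is expected to co-cluster
  with GU-phenotype samples ("convergence");
* BASAL_SCC samples are split by a bimodal ECM amplitude between a
  mesenchymal-infiltrated context and a low-infiltration context
  ("divergence");
* very low-purity URO/GU samples form an epithelial-infiltrated context;
* SCNE_LIKE samples plus amplicon-positive, highly proliferative GU samples
  form the small-cell/neuroendocrine context.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    CONTEXTS,
    ExpressionMatrix,
    GeneSetCollection,
    IHCTable,
    LabelTable,
    PHENOTYPES,
    ValidationError,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "planted_truth",
    "GENE_BLOCKS",
    "MARKER_GENE_MAP",
]

# --------------------------------------------------------------------------
# Gene universe
# --------------------------------------------------------------------------

URO_DIFF_GENES = (
    "UPK1A", "UPK1B", "UPK2", "UPK3A", "KRT20",
    "PPARG", "RXRA", "ELF3", "FOXA1", "GATA3",
    "UPK3B", "KRT7", "KRT8", "KRT18", "KRT19", "SNX31", "ERBB2", "ERBB3",
    "TBX2", "TBX3", "CYP2J2", "ADIRF", "SPINK1", "DHRS2", "VSIG2",
)
FGFR3_CLUSTER_GENES = ("FGFR3", "CCND1", "TP63")
CIRCUIT_EXTRA_GENES = ("RB1", "E2F3", "CDKN2A")
SCC_GENES = (
    "KRT5", "KRT14", "KRT6A", "KRT6B", "DSC2", "KRT16", "SERPINB3", "PI3",
    "KRT6C", "KRT13", "SPRR1A", "SPRR1B", "SPRR2A", "SPRR3", "IVL", "TGM1",
    "S100A7", "S100A8", "DSC3", "CSTA",
)
NE_GENES = ("CHGA", "SYP", "ENO2", "NCAM1", "TUBB2B", "TUBB2A")
EMT_GENES = ("VIM", "ZEB2", "CDH1", "CDH3", "EPCAM")
AMPLICON_GENES = ("E2F3", "CDKAL1", "SOX4", "MBOAT1")
PROLIF_GENES = (
    "CCNB1", "CCNB2", "CDK1", "PLK1", "BUB1", "AURKA", "AURKB", "TOP2A",
    "MKI67", "FOXM1", "CDC20", "CENPA", "CENPE", "CENPF", "KIF11", "KIF23",
    "KIF2C", "CCNA2", "CDC6", "CDC45", "E2F7", "ESPL1", "MCM2", "MCM10",
    "NDC80", "PTTG1", "RRM2", "TTK", "TYMS", "UBE2C",
    "CDKN3", "TPX2", "MELK", "DLGAP5", "PRC1", "ANLN", "NUSAP1", "ASPM",
    "RACGAP1", "TROAP",
)
TCELL_GENES = (
    "CD2", "CD3D", "CD3E", "CD3G", "CD8A", "LCK", "ZAP70", "IL2RB", "GZMB",
    "PRF1", "CD247", "CD27", "CD28", "CCL5", "CXCL9", "CXCL10", "IL7R",
    "ITK", "SH2D1A", "TRAT1",
    "CD4", "CTLA4", "ICOS", "GZMA", "GZMK", "NKG7", "KLRD1", "CST7",
    "TBX21", "EOMES", "CXCR3", "CCR5", "IL21R", "SIRPG", "CD96",
)
ECM_GENES = (
    "COL1A1", "COL1A2", "COL3A1", "COL5A1", "COL5A2", "COL6A1", "COL6A2",
    "COL6A3", "FN1", "LUM", "POSTN", "SPARC", "DCN", "FBN1", "THBS1",
    "THBS2", "VCAN", "FAP", "PDGFRB", "ACTA2", "BGN", "MMP2", "SULF1",
    "AEBP1", "OLFML2B", "COL8A1", "COL10A1", "COL11A1", "CTHRC1", "INHBA",
    "COL4A1", "COL4A2", "COL15A1", "MMP11", "MMP14", "TIMP2", "LOX",
    "LOXL1", "LOXL2", "FBLN1", "FBLN2", "MXRA8", "SERPINF1", "ISLR",
    "COL14A1",
)

GENE_BLOCKS: dict[str, tuple[str, ...]] = {
    "URO_DIFF": URO_DIFF_GENES,
    "FGFR3_CLUSTER": FGFR3_CLUSTER_GENES,
    "SCC": SCC_GENES,
    "NE": NE_GENES,
    "LATE_CELL_CYCLE": PROLIF_GENES,
    "TCELL": TCELL_GENES,
    "ECM": ECM_GENES,
    "AMPLICON_6P22": AMPLICON_GENES,
}

#: IHC marker name -> gene id carrying its tumour-cell value.
MARKER_GENE_MAP: dict[str, str] = {
    "CCNB1": "CCNB1", "CCND1": "CCND1", "CDH1": "CDH1", "CDH3": "CDH3",
    "CDKN2A": "CDKN2A", "CHGA": "CHGA", "E2F3": "E2F3", "EPCAM": "EPCAM",
    "FGFR3": "FGFR3", "FOXA1": "FOXA1", "GATA3": "GATA3", "KRT5": "KRT5",
    "KRT14": "KRT14", "KRT20": "KRT20", "NCAM1": "NCAM1", "PPARG": "PPARG",
    "RB1": "RB1", "RXRA": "RXRA", "SYP": "SYP", "TP63": "TP63",
    "TUBB2B": "TUBB2B", "UPK3": "UPK3A", "VIM": "VIM", "ZEB2": "ZEB2",
}

#: log2 expression levels used to build mean profiles.  Marker contrasts are
#: kept at realistic array effect sizes (~2.5 log2 between clearly positive
#: and clearly negative tumour cells) so that a handful of marker genes
#: cannot dominate global clustering the way whole infiltration or
#: proliferation programmes can.  LOW2 marks lineage markers whose
#: negativity must survive discretisation with margin.
HIGH, MIDHIGH, MID, BASE, LOW2 = 7.0, 6.8, 6.5, 4.5, 4.0

#: background tumour baseline for lineage-threshold markers
_LINEAGE_LOW = {
    "KRT5": LOW2, "KRT14": LOW2, "VIM": LOW2, "ZEB2": LOW2,
    "TUBB2B": LOW2, "CHGA": LOW2, "SYP": LOW2, "NCAM1": LOW2,
}


def _tumour_profiles() -> dict[str, dict[str, float]]:
    """Mean tumour-cell log2 profile per phenotype over the signal genes."""
    profiles: dict[str, dict[str, float]] = {}
    signal = set().union(*GENE_BLOCKS.values(), EMT_GENES, CIRCUIT_EXTRA_GENES)

    def base_profile() -> dict[str, float]:
        prof = {g: BASE for g in signal}
        prof.update(_LINEAGE_LOW)
        for g in PROLIF_GENES:
            prof[g] = 5.0  # proliferation enters through the amplitude
        return prof

    uro = base_profile()
    uro.update({g: HIGH for g in URO_DIFF_GENES})
    uro.update({"FGFR3": HIGH, "CCND1": HIGH, "TP63": HIGH, "RB1": MIDHIGH})
    uro.update({"E2F3": BASE, "CDKN2A": BASE})
    uro.update({"CDH1": HIGH, "EPCAM": HIGH, "CDH3": BASE})
    profiles["URO"] = uro

    gu = base_profile()
    gu.update({g: MID for g in URO_DIFF_GENES})
    gu.update({"FOXA1": MIDHIGH, "GATA3": MIDHIGH})
    gu.update({"FGFR3": BASE, "CCND1": BASE, "TP63": 5.5, "RB1": BASE})
    gu.update({"E2F3": MIDHIGH, "CDKN2A": HIGH})
    gu.update({"CDH1": HIGH, "EPCAM": HIGH, "CDH3": 5.0})
    profiles["GU"] = gu

    basal = base_profile()
    basal.update({g: MIDHIGH for g in SCC_GENES})
    basal.update({"KRT5": HIGH, "KRT14": MIDHIGH, "TP63": HIGH})
    basal.update({"FOXA1": BASE, "GATA3": BASE})
    basal.update({"FGFR3": BASE, "CCND1": BASE, "RB1": 6.3})
    basal.update({"E2F3": 5.5, "CDKN2A": 5.5})
    basal.update({"CDH1": 5.6, "EPCAM": 6.3, "CDH3": HIGH})
    profiles["BASAL_SCC"] = basal

    mes = base_profile()
    mes.update({"VIM": HIGH, "ZEB2": HIGH})
    mes.update({"CDH1": BASE, "EPCAM": BASE, "CDH3": BASE})
    mes.update({"FOXA1": BASE, "GATA3": BASE, "TP63": BASE})
    mes.update({"FGFR3": BASE, "CCND1": BASE, "RB1": 6.3})
    mes.update({"E2F3": 5.5, "CDKN2A": 5.5})
    profiles["MES_LIKE"] = mes

    scne = base_profile()
    scne.update({g: MID for g in NE_GENES})
    scne.update({"TUBB2B": HIGH, "CHGA": HIGH, "SYP": HIGH, "NCAM1": HIGH})
    scne.update({"FOXA1": BASE, "GATA3": BASE, "TP63": BASE})
    scne.update({"FGFR3": BASE, "CCND1": BASE, "RB1": BASE})
    scne.update({"E2F3": MIDHIGH, "CDKN2A": MID})
    scne.update({"CDH1": 6.3, "EPCAM": 6.3, "CDH3": 5.0})
    profiles["SCNE_LIKE"] = scne

    return profiles


@dataclass(frozen=True)
class ContextParams:
    """Distribution of the context covariates within one expression context."""

    purity_beta: tuple[float, float]
    ecm: tuple[float, float]  # (mean, sd) of the ECM/stromal amplitude, log2
    tcell: tuple[float, float]
    prolif: tuple[float, float]


_DEFAULT_CONTEXT_PARAMS: dict[str, ContextParams] = {
    "Uro": ContextParams((32, 8), (0.5, 0.3), (0.5, 0.3), (0.4, 0.3)),
    "GU": ContextParams((20, 8), (2.2, 0.3), (2.2, 0.3), (3.0, 0.3)),
    "EpiInf": ContextParams((8, 16), (3.8, 0.3), (6.0, 0.4), (1.5, 0.3)),
    "SCCL_MesInf": ContextParams((12, 12), (4.8, 0.4), (2.0, 0.3), (2.5, 0.3)),
    "SCCL_UroB": ContextParams((32, 8), (1.0, 0.3), (1.0, 0.3), (2.0, 0.3)),
    "ScNE": ContextParams((24, 8), (0.8, 0.3), (0.8, 0.3), (6.0, 0.4)),
}

#: P(context | phenotype).  URO samples spread over three luminal contexts
#: (planting Uro/GU convergence); BASAL_SCC is split by infiltration
#: (planting divergence); GU spreads over GU, Epi-Inf and Sc/NE contexts.
_DEFAULT_CONTEXT_PROBS: dict[str, dict[str, float]] = {
    "URO": {"Uro": 0.36, "GU": 0.38, "EpiInf": 0.26},
    "GU": {"GU": 0.55, "EpiInf": 0.25, "ScNE": 0.20},
    "BASAL_SCC": {"SCCL_MesInf": 0.5, "SCCL_UroB": 0.5},
    "MES_LIKE": {"SCCL_MesInf": 1.0},
    "SCNE_LIKE": {"ScNE": 1.0},
}

_DEFAULT_PHENOTYPE_PROPS: dict[str, float] = {
    "URO": 0.34,
    "GU": 0.26,
    "BASAL_SCC": 0.22,
    "MES_LIKE": 0.08,
    "SCNE_LIKE": 0.10,
}


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate a cystectomy cohort of ~300 advanced tumours: five
    phenotypes in the proportions above, six expression contexts, tumour
    purity drawn per context (overall centred near 0.7), Gaussian log2
    noise on bulk arrays, and an ordinal 0-3 IHC read-out of the tumour
    component with a small missingness rate.
    """

    n_samples: int = 300
    phenotype_props: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PHENOTYPE_PROPS)
    )
    context_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CONTEXT_PROBS.items()}
    )
    context_params: Mapping[str, ContextParams] = field(
        default_factory=lambda: dict(_DEFAULT_CONTEXT_PARAMS)
    )
    #: P(6p22 amplicon | phenotype, context); ScNE-context samples always
    #: carry it, GU-phenotype samples elsewhere with moderate probability.
    amplicon_prob_gu: float = 0.10
    amplicon_boost: float = 3.0
    expr_noise_sd: float = 0.35
    ihc_noise_sd: float = 0.5
    ihc_missing_rate: float = 0.02
    ihc_cutpoints: tuple[float, float, float] = (5.2, 5.9, 6.6)
    n_noise_genes: int = 185
    purity_fixed: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.phenotype_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"phenotype proportions sum to {total}, not 1")
        if set(self.phenotype_props) - set(PHENOTYPES):
            raise ValidationError("unknown phenotype in proportions")
        for phen, probs in self.context_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValidationError(f"context probabilities for {phen} do not sum to 1")
            if set(probs) - set(CONTEXTS):
                raise ValidationError(f"unknown context for {phen}")
        if self.expr_noise_sd < 0 or self.ihc_noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        if not (0.0 <= self.ihc_missing_rate < 1.0):
            raise ValidationError("missingness must be in [0, 1)")
        if self.purity_fixed is not None and not (0.0 < self.purity_fixed <= 1.0):
            raise ValidationError("purity must be in (0, 1]")
        if list(self.ihc_cutpoints) != sorted(self.ihc_cutpoints):
            raise ValidationError("IHC cutpoints must be increasing")

    def noise_free(self) -> "CohortConfig":
        """Copy with all stochastic corruption switched off (purity untouched)."""
        return replace(self, expr_noise_sd=0.0, ihc_noise_sd=0.0, ihc_missing_rate=0.0)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    expression: ExpressionMatrix
    ihc: IHCTable
    phenotypes: LabelTable
    contexts: LabelTable
    purity: pd.Series
    covariates: pd.DataFrame  # ecm_amp, tcell_amp, prolif_amp, amplicon
    gene_sets: GeneSetCollection
    config: CohortConfig


def _draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=size), 0.0, None)


def generate_cohort(config: Optional[CohortConfig] = None) -> SyntheticCohort:
    """Draw a full synthetic cohort from the configured generative model."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    phen_names = [p for p in PHENOTYPES if p in config.phenotype_props]
    phen_probs = np.array([config.phenotype_props[p] for p in phen_names])
    phenotypes = rng.choice(phen_names, size=n, p=phen_probs)

    contexts = np.empty(n, dtype=object)
    for i, phen in enumerate(phenotypes):
        probs = config.context_probs[phen]
        names = list(probs)
        contexts[i] = rng.choice(names, p=np.array([probs[c] for c in names]))

    purity = np.empty(n)
    ecm_amp = np.empty(n)
    tcell_amp = np.empty(n)
    prolif_amp = np.empty(n)
    for i in range(n):
        cp = config.context_params[contexts[i]]
        purity[i] = (
            config.purity_fixed
            if config.purity_fixed is not None
            else np.clip(rng.beta(*cp.purity_beta), 0.05, 1.0)
        )
        ecm_amp[i] = _draw_truncated_normal(rng, *cp.ecm, 1)[0]
        tcell_amp[i] = _draw_truncated_normal(rng, *cp.tcell, 1)[0]
        prolif_amp[i] = _draw_truncated_normal(rng, *cp.prolif, 1)[0]

    amplicon = np.zeros(n, dtype=int)
    for i in range(n):
        if contexts[i] == "ScNE":
            amplicon[i] = 1
        elif phenotypes[i] == "GU":
            amplicon[i] = int(rng.random() < config.amplicon_prob_gu)

    profiles = _tumour_profiles()
    signal_genes = sorted(set().union(*GENE_BLOCKS.values(), EMT_GENES, CIRCUIT_EXTRA_GENES))
    noise_genes = [f"NOISE{i + 1:04d}" for i in range(config.n_noise_genes)]
    genes = signal_genes + noise_genes
    g_index = {g: j for j, g in enumerate(genes)}
    n_genes = len(genes)

    # per-phenotype tumour profile matrix over the gene universe
    tumour_base = np.full((len(phen_names), n_genes), BASE)
    for pi, phen in enumerate(phen_names):
        for g, v in profiles[phen].items():
            tumour_base[pi, g_index[g]] = v
    phen_idx = np.array([phen_names.index(p) for p in phenotypes])

    prolif_mask = np.zeros(n_genes)
    for g in PROLIF_GENES:
        prolif_mask[g_index[g]] = 1.0
    amplicon_mask = np.zeros(n_genes)
    for g in AMPLICON_GENES:
        amplicon_mask[g_index[g]] = 1.0
    ecm_mask = np.zeros(n_genes)
    for g in ECM_GENES:
        ecm_mask[g_index[g]] = 1.0
    tcell_mask = np.zeros(n_genes)
    for g in TCELL_GENES:
        tcell_mask[g_index[g]] = 1.0

    stroma_base = np.full(n_genes, BASE)
    stroma_base[g_index["VIM"]] = 8.0  # stromal cells are constitutively VIM+
    stroma_base[g_index["ZEB2"]] = 7.5
    for g in ECM_GENES:
        stroma_base[g_index[g]] = 5.0

    tumour = (
        tumour_base[phen_idx]
        + prolif_amp[:, None] * prolif_mask[None, :]
        + config.amplicon_boost * amplicon[:, None] * amplicon_mask[None, :]
    )
    stroma = (
        stroma_base[None, :]
        + ecm_amp[:, None] * ecm_mask[None, :]
        + tcell_amp[:, None] * tcell_mask[None, :]
    )
    bulk = purity[:, None] * tumour + (1.0 - purity[:, None]) * stroma
    if config.expr_noise_sd > 0:
        bulk = bulk + rng.normal(0.0, config.expr_noise_sd, size=bulk.shape)

    expression = ExpressionMatrix(
        pd.DataFrame(bulk.T, index=genes, columns=sample_ids)
    )

    # IHC: discretised tumour component only
    markers = sorted(MARKER_GENE_MAP)
    marker_cols = np.array([g_index[MARKER_GENE_MAP[m]] for m in markers])
    tumour_marker = tumour[:, marker_cols]
    if config.ihc_noise_sd > 0:
        tumour_marker = tumour_marker + rng.normal(
            0.0, config.ihc_noise_sd, size=tumour_marker.shape
        )
    cut = np.array(config.ihc_cutpoints)
    intensities = np.digitize(tumour_marker, cut).astype(float)
    if config.ihc_missing_rate > 0:
        missing = rng.random(intensities.shape) < config.ihc_missing_rate
        intensities[missing] = np.nan
    ihc = IHCTable(pd.DataFrame(intensities, index=sample_ids, columns=markers))

    gene_sets = GeneSetCollection(
        {name: genes_ for name, genes_ in GENE_BLOCKS.items()},
        provenance={name: "synthetic ground-truth block" for name in GENE_BLOCKS},
    )

    phenotype_table = LabelTable(
        pd.Series(phenotypes, index=sample_ids, name="phenotype"),
        vocabulary=PHENOTYPES,
    )
    context_table = LabelTable(
        pd.Series(contexts, index=sample_ids, name="context"),
        vocabulary=CONTEXTS,
    )
    covariates = pd.DataFrame(
        {
            "ecm_amp": ecm_amp,
            "tcell_amp": tcell_amp,
            "prolif_amp": prolif_amp,
            "amplicon": amplicon,
        },
        index=sample_ids,
    )
    return SyntheticCohort(
        expression=expression,
        ihc=ihc,
        phenotypes=phenotype_table,
        contexts=context_table,
        purity=pd.Series(purity, index=sample_ids, name="purity"),
        covariates=covariates,
        gene_sets=gene_sets,
        config=config,
    )


def planted_truth(cohort: SyntheticCohort) -> tuple[LabelTable, LabelTable]:
    """Ground-truth (phenotype, context) label tables; pure accessor."""
    return cohort.phenotypes, cohort.contexts
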