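"""End-to-end orchestration: simulate -> score -> phenotype -> cluster ->
deconstruct -> concord, as one reproducible run.

A run is driven by a single :class:`RunConfig` holding either a simulation
configuration or paths to precomputed inputs, plus the parameter blocks of
every stage and a seed.  All outputs are written below one directory and a
manifest records the paths, the metrics, the seed and a hash of the full
configuration; every tabular output carries that hash in a ``#`` header
comment so a result file can always be traced to its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .concordance import (
    DeconstructionMap,
    PHENOTYPE_TO_CLASS,
    confusion_summary,
    crosstab_report,
    deconstruct,
)
from .consensus import SplitParams, sequential_splits
from .phenotype import RuleParams, classify_cohort
from .scores import (
    basq_score_from_expr,
    basq_score_from_ihc,
    circuit_score_from_expr,
    circuit_score_from_ihc,
    signature_score,
    variance_filter,
)
from .simulate import CohortConfig, SyntheticCohort, generate_cohort
from .types import (
    DECONSTRUCTED_CLASSES,
    LabelTable,
    PhenoclassError,
    UNCLASSIFIED,
    ValidationError,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(PhenoclassError):
    """A stage failed; the message names the stage and the offending item."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` and ``expression_path``/``ihc_path`` must
    be provided.  When ``cluster_labels_path`` is given, clustering is
    skipped and concordance is computed against the provided labels.
    """

    outdir: str = "phenoclass_run"
    seed: int = 0
    simulation: Optional[CohortConfig] = None
    expression_path: Optional[str] = None
    ihc_path: Optional[str] = None
    cluster_labels_path: Optional[str] = None
    reference_phenotypes_path: Optional[str] = None
    variance_fraction: float = 0.5
    rules: RuleParams = field(default_factory=RuleParams)
    split: SplitParams = field(default_factory=SplitParams)
    unclassified_as_error: bool = False

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_paths = self.expression_path is not None or self.ihc_path is not None
        if has_sim and has_paths:
            raise ValidationError("provide either a simulation config or input paths, not both")
        if not has_sim and self.ihc_path is None:
            raise ValidationError("an IHC table (or a simulation config) is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        rules = raw.pop("rules", None)
        split = raw.pop("split", None)
        cfg = cls(
            simulation=CohortConfig(**sim) if sim is not None else None,
            rules=RuleParams(**rules) if rules else RuleParams(),
            split=SplitParams(**split) if split else SplitParams(),
            **raw,
        )
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _name_leaves_by_context(
    cluster_labels: LabelTable, contexts: LabelTable
) -> LabelTable:
    """Rename tree leaves by the majority latent context of their members.

    Two leaves dominated by the same context get suffixed names so the
    vocabulary stays unique.
    """
    cl, ctx = cluster_labels.align_with(contexts)
    mapping: dict[str, str] = {}
    used: dict[str, int] = {}
    for leaf in sorted(set(cl.dropna())):
        members = ctx[cl == leaf].dropna()
        majority = members.mode().iloc[0] if len(members) else leaf
        used[majority] = used.get(majority, 0) + 1
        mapping[leaf] = majority if used[majority] == 1 else f"{majority}.{used[majority]}"
    renamed = cl.map(mapping)
    return LabelTable(renamed, vocabulary=tuple(dict.fromkeys(mapping.values())))


def _phenotype_to_class_labels(phenotypes: LabelTable) -> LabelTable:
    mapped = phenotypes.labels.map(lambda v: PHENOTYPE_TO_CLASS.get(v, np.nan))
    return LabelTable(mapped, vocabulary=DECONSTRUCTED_CLASSES)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"config_hash={chash} seed={config.seed}"
    manifest: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "outputs": {},
        "metrics": {},
    }

    def out(name: str) -> Path:
        p = outdir / name
        manifest["outputs"][name.split(".")[0]] = str(p)
        return p

    # ---- stage: inputs -----------------------------------------------------
    cohort: Optional[SyntheticCohort] = None
    truth_phen: Optional[LabelTable] = None
    truth_ctx: Optional[LabelTable] = None
    try:
        if config.simulation is not None:
            sim_cfg = config.simulation
            if sim_cfg.seed != config.seed:
                sim_cfg = CohortConfig(**{**asdict_shallow(sim_cfg), "seed": config.seed})
            cohort = generate_cohort(sim_cfg)
            expression, ihc = cohort.expression, cohort.ihc
            truth_phen, truth_ctx = cohort.phenotypes, cohort.contexts
            pio.write_expression_matrix(expression, out("expression.tsv"), header)
            pio.write_ihc_table(ihc, out("ihc.csv"), header)
            pio.write_label_table(truth_phen, out("truth_phenotypes.tsv"), header)
            pio.write_label_table(truth_ctx, out("truth_contexts.tsv"), header)
            pio.write_gene_sets(cohort.gene_sets, out("gene_sets.gmt"))
        else:
            expression = (
                pio.read_expression_matrix(config.expression_path)
                if config.expression_path
                else None
            )
            ihc = pio.read_ihc_table(config.ihc_path)
    except PhenoclassError as exc:
        raise PipelineError(f"stage 'inputs': {exc}") from exc

    # ---- stage: scores -----------------------------------------------------
    try:
        score_rows = []
        for sv in filter(None, [
            circuit_score_from_ihc(ihc),
            basq_score_from_ihc(ihc),
            circuit_score_from_expr(expression) if expression is not None else None,
            basq_score_from_expr(expression) if expression is not None else None,
        ]):
            for sample, value in sv.values.items():
                score_rows.append((sample, sv.score_name, sv.level, value))
        if cohort is not None:
            for name in cohort.gene_sets.names():
                sv = signature_score(expression, cohort.gene_sets[name], name)
                for sample, value in sv.values.items():
                    score_rows.append((sample, sv.score_name, sv.level, value))
        scores_df = pd.DataFrame(
            score_rows, columns=["sample_id", "score_name", "level", "value"]
        )
        with open(out("scores.tsv"), "w") as fh:
            fh.write(f"# {header}\n")
            scores_df.to_csv(fh, sep="\t", index=False)
    except PhenoclassError as exc:
        raise PipelineError(f"stage 'scores': {exc}") from exc

    # ---- stage: phenotype --------------------------------------------------
    try:
        classification = classify_cohort(ihc, config.rules)
        pio.write_label_table(
            classification.labels, out("phenotype_calls.tsv"), header, "phenotype"
        )
        evidence = {c.sample_id: {"phenotype": c.phenotype, "rule": c.rule_fired, **c.evidence}
                    for c in classification.calls}
        with open(out("phenotype_evidence.json"), "w") as fh:
            json.dump({"config_hash": chash, "samples": evidence}, fh, indent=1)
    except PhenoclassError as exc:
        raise PipelineError(f"stage 'phenotype': {exc}") from exc

    # ---- stage: cluster ----------------------------------------------------
    try:
        if config.cluster_labels_path is not None:
            cluster_labels = pio.read_label_table(config.cluster_labels_path)
            tree = None
        elif expression is not None:
            filtered = variance_filter(expression, config.variance_fraction)
            tree = sequential_splits(filtered, config.split, seed=config.seed)
            cluster_labels = tree.labels()
            with open(out("cluster_tree.json"), "w") as fh:
                json.dump({"config_hash": chash, **tree.to_dict()}, fh, indent=1)
        else:
            cluster_labels = None
            tree = None
        if cluster_labels is not None and truth_ctx is not None:
            cluster_labels = _name_leaves_by_context(cluster_labels, truth_ctx)
        if cluster_labels is not None:
            pio.write_label_table(
                cluster_labels, out("cluster_labels.tsv"), header, "cluster"
            )
            manifest["metrics"]["n_clusters"] = len(set(cluster_labels.labels.dropna()))
    except PhenoclassError as exc:
        raise PipelineError(f"stage 'cluster': {exc}") from exc

    # ---- stage: deconstruct + concord -------------------------------------
    try:
        if cluster_labels is not None:
            if config.reference_phenotypes_path is not None:
                ref_phen = pio.read_label_table(config.reference_phenotypes_path)
            elif truth_phen is not None:
                ref_phen = truth_phen
            else:
                ref_phen = classification.labels
            reference = deconstruct(cluster_labels, ref_phen, DeconstructionMap.default())
            predicted = _phenotype_to_class_labels(classification.labels)
            summary = confusion_summary(
                reference,
                predicted,
                unclassified_as_error=config.unclassified_as_error,
            )
            with open(out("confusion.tsv"), "w") as fh:
                fh.write(f"# {header}\n")
                summary.counts.to_csv(fh, sep="\t")
            manifest["metrics"]["concordance"] = summary.to_dict()
            xtab = crosstab_report(cluster_labels, classification.labels)
            with open(out("crosstab.tsv"), "w") as fh:
                fh.write(f"# {header}\n")
                xtab.to_csv(fh, sep="\t")
    except PhenoclassError as exc:
        raise PipelineError(f"stage 'concordance': {exc}") from exc

    # ---- metrics against planted truth ------------------------------------
    if truth_phen is not None:
        truth, called = truth_phen.align_with(classification.labels)
        classified = called != UNCLASSIFIED
        agree = (truth[classified] == called[classified]).mean()
        manifest["metrics"]["phenotype_recovery"] = {
            "accuracy_classified": float(agree),
            "fraction_unclassified": float((~classified).mean()),
        }

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline run complete: %s", outdir)
    return manifest


def asdict_shallow(cfg: CohortConfig) -> dict:
    """dataclasses.asdict without deep-copying the nested mappings."""
    return {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
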