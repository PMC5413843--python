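import numpy as np
import pandas as pd
import pytest

from phenoclass.concordance import (
    DeconstructionMap,
    confusion_summary,
    crosstab_report,
    deconstruct,
)
from phenoclass.types import LabelTable, UNCLASSIFIED, ValidationError

PHEN_VOCAB = ("URO", "GU", "BASAL_SCC", "MES_LIKE", "SCNE_LIKE", UNCLASSIFIED)
CLASS_VOCAB = ("Uro", "GU", "BasalSCC", "MesLike", "ScNELike")


def labels(mapping, vocab):
    return LabelTable(pd.Series(mapping, dtype=object), vocab)


class TestDeconstruct:
    def test_published_regrouping_rules(self):
        clusters = labels(
            {"a": "GU", "b": "ScNE", "c": "Uro", "d": "SCCL_UroB", "e": "SCCL_MesInf"},
            ("Uro", "GU", "EpiInf", "SCCL_MesInf", "SCCL_UroB", "ScNE"),
        )
        phen = labels(
            {"a": "URO", "b": "GU", "c": UNCLASSIFIED, "d": "BASAL_SCC", "e": "MES_LIKE"},
            PHEN_VOCAB,
        )
        out = deconstruct(clusters, phen).labels
        assert out["a"] == "Uro"      # GU-cluster Uro phenotype counts as Uro
        assert out["b"] == "GU"       # Sc/NE-cluster GU phenotype counts as GU
        assert pd.isna(out["c"])      # unclassified propagates to missing
        assert out["d"] == "BasalSCC"
        assert out["e"] == "MesLike"

    def test_sample_mismatch_lists_difference(self):
        clusters = labels({"a": "GU"}, ("GU",))
        phen = labels({"b": "URO"}, PHEN_VOCAB)
        with pytest.raises(ValidationError, match="symmetric difference"):
            deconstruct(clusters, phen)

    def test_unmapped_combination_is_missing(self):
        clusters = labels({"a": "Uro"}, ("Uro",))
        phen = labels({"a": "SCNE_LIKE"}, PHEN_VOCAB)
        assert pd.isna(deconstruct(clusters, phen).labels["a"])


class TestConfusionSummary:
    def test_identity_prediction_is_perfect(self):
        ref = labels({f"s{i}": CLASS_VOCAB[i % 3] for i in range(9)}, CLASS_VOCAB)
        summary = confusion_summary(ref, ref)
        assert summary.overall_accuracy == 1.0
        assert all(v == 1.0 for v in summary.sensitivity.values())
        assert all(v == 1.0 for v in summary.specificity.values())

    def test_hand_counted_two_class_metrics(self):
        # class A: TP=8 FN=2; class B: FP=1 TN=9 -> sens .8, spec .9, acc .85
        ref, pred = {}, {}
        for i in range(10):
            ref[f"a{i}"] = "Uro"
            pred[f"a{i}"] = "Uro" if i < 8 else "GU"
        for i in range(10):
            ref[f"b{i}"] = "GU"
            pred[f"b{i}"] = "GU" if i < 9 else "Uro"
        summary = confusion_summary(
            labels(ref, CLASS_VOCAB), labels(pred, CLASS_VOCAB)
        )
        assert summary.overall_accuracy == pytest.approx(0.85)
        assert summary.sensitivity["Uro"] == pytest.approx(0.8)
        assert summary.specificity["Uro"] == pytest.approx(0.9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(60)]
        ref_vals = rng.choice(["Uro", "GU", "BasalSCC"], size=60)
        pred_vals = rng.choice(["Uro", "GU", "BasalSCC", None], size=60)
        ref = labels(dict(zip(ids, ref_vals)), CLASS_VOCAB)
        pred = labels(dict(zip(ids, pred_vals)), CLASS_VOCAB)
        summary = confusion_summary(ref, pred)
        both = [i for i in ids if pred.labels[i] is not None]
        acc = np.mean([ref.labels[i] == pred.labels[i] for i in both])
        assert summary.overall_accuracy == pytest.approx(acc)
        for c in summary.vocabulary:
            tp = sum(1 for i in both if ref.labels[i] == c and pred.labels[i] == c)
            fn = sum(1 for i in both if ref.labels[i] == c and pred.labels[i] != c)
            fp = sum(1 for i in both if ref.labels[i] != c and pred.labels[i] == c)
            tn = sum(1 for i in both if ref.labels[i] != c and pred.labels[i] != c)
            if tp + fn:
                assert summary.sensitivity[c] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert summary.specificity[c] == pytest.approx(tn / (tn + fp))
        assert summary.counts.to_numpy().sum() == summary.n_classified == len(both)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(30)]
        ref_vals = rng.choice(["Uro", "GU"], size=30)
        pred_vals = rng.choice(["Uro", "GU"], size=30)
        ref = labels(dict(zip(ids, ref_vals)), CLASS_VOCAB)
        pred = labels(dict(zip(ids, pred_vals)), CLASS_VOCAB)
        perm = list(rng.permutation(ids))
        ref_p = LabelTable(ref.labels.loc[perm], CLASS_VOCAB)
        pred_p = LabelTable(pred.labels.loc[perm], CLASS_VOCAB)
        a = confusion_summary(ref, pred)
        b = confusion_summary(ref_p, pred_p)
        assert a.overall_accuracy == b.overall_accuracy
        assert a.sensitivity == b.sensitivity

    def test_unclassified_as_error_mode(self):
        ref = labels({"a": "Uro", "b": "Uro", "c": "GU"}, CLASS_VOCAB)
        pred = labels({"a": "Uro", "b": UNCLASSIFIED, "c": "GU"}, CLASS_VOCAB + (UNCLASSIFIED,))
        lenient = confusion_summary(ref, pred)
        strict = confusion_summary(ref, pred, unclassified_as_error=True)
        assert lenient.overall_accuracy == 1.0
        assert strict.overall_accuracy == pytest.approx(2 / 3)
        assert strict.sensitivity["Uro"] == pytest.approx(0.5)

    def test_empty_intersection_is_error(self):
        ref = labels({"a": "Uro"}, CLASS_VOCAB)
        pred = labels({"a": None}, CLASS_VOCAB)
        with pytest.raises(ValidationError):
            confusion_summary(ref, pred)


class TestCrosstab:
    def test_disjoint_labels_are_diagonal(self):
        clusters = labels({"a": "Uro", "b": "GU"}, ("Uro", "GU"))
        phen = labels({"a": "URO", "b": "GU"}, PHEN_VOCAB)
        table = crosstab_report(clusters, phen)
        assert table.loc["Uro", "URO"] == 1 and table.loc["GU", "GU"] == 1
        assert table.to_numpy().sum() == 2

    def test_rows_sum_to_cluster_sizes(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(50)]
        cl_vals = rng.choice(["Uro", "GU", "ScNE"], size=50)
        ph_vals = rng.choice(["URO", "GU", UNCLASSIFIED], size=50)
        clusters = labels(dict(zip(ids, cl_vals)), ("Uro", "GU", "ScNE"))
        phen = labels(dict(zip(ids, ph_vals)), PHEN_VOCAB)
        table = crosstab_report(clusters, phen)
        sizes = clusters.labels.value_counts()
        for cluster in table.index:
            assert table.loc[cluster].sum() == sizes[cluster]
        assert UNCLASSIFIED in table.columns
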