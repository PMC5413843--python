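import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phenoclass.scores import (
    ScoreVector,
    basq_score,
    circuit_score,
    percentile_map,
    signature_score,
    variance_filter,
)
from phenoclass.types import ValidationError

from conftest import make_expr


def series(values, samples=None):
    samples = samples or [f"S{i + 1}" for i in range(len(values))]
    return pd.Series(values, index=samples, dtype=float)


class TestSignatureScore:
    def test_mean_of_two_genes(self):
        em = make_expr([[2.0], [4.0]], genes=["A", "B"])
        sv = signature_score(em, ["A", "B"])
        assert sv.values.iloc[0] == 3.0

    def test_single_gene_is_identity(self):
        em = make_expr([[1.0, 5.0], [9.0, 9.0]], genes=["A", "B"])
        sv = signature_score(em, ["A"])
        assert list(sv.values) == [1.0, 5.0]

    def test_absent_genes_ignored_matches_bruteforce(self):
        em = make_expr([[2.0, 1.0], [6.0, 3.0]], genes=["A", "B"])
        with pytest.warns(UserWarning, match="absent"):
            sv = signature_score(em, ["A", "B", "MISSING_GENE"])
        # oracle: explicit loop over present genes
        for j, sample in enumerate(em.sample_ids):
            expected = np.mean([em.values.iloc[0, j], em.values.iloc[1, j]])
            assert sv.values[sample] == expected

    def test_no_gene_present_is_error(self):
        em = make_expr([[1.0]], genes=["A"])
        with pytest.raises(ValidationError, match="X1"):
            signature_score(em, ["X1", "X2"])


class TestCompositeScores:
    @pytest.mark.parametrize(
        "f, c, r, e, expected",
        [
            (0, 0, 0, 0, 0.0),
            (3, 3, 3, 0, 9.0),
            (0, 0, 0, 3, -3.0),
            (2.5, 1.0, 1.5, 4.0, 1.0),
        ],
    )
    def test_circuit_values(self, f, c, r, e, expected):
        sv = circuit_score(series([f]), series([c]), series([r]), series([e]), "IHC")
        assert sv.values.iloc[0] == expected

    @pytest.mark.parametrize(
        "fo, g, k5, k14, expected",
        [
            (0, 0, 3, 3, -6.0),  # basal/SCC-like direction is low
            (3, 3, 0, 0, 6.0),
            (2, 2, 2, 2, 0.0),
        ],
    )
    def test_basq_values(self, fo, g, k5, k14, expected):
        sv = basq_score(series([fo]), series([g]), series([k5]), series([k14]), "IHC")
        assert sv.values.iloc[0] == expected

    def test_missing_component_propagates(self):
        sv = circuit_score(
            series([np.nan, 1.0]), series([1, 1]), series([1, 1]), series([0, 0]), "IHC"
        )
        assert np.isnan(sv.values.iloc[0]) and sv.values.iloc[1] == 3.0

    def test_misaligned_samples_error(self):
        with pytest.raises(ValidationError, match="aligned"):
            circuit_score(
                series([1], ["S1"]), series([1], ["S2"]), series([1], ["S1"]),
                series([1], ["S1"]),
            )

    def test_monotone_in_each_component(self):
        # circuit strictly increases in FGFR3/CCND1/RB1 and decreases in E2F3
        rng = np.random.default_rng(0)
        for _ in range(20):
            f, c, r, e = (series(rng.normal(size=5)) for _ in range(4))
            base = circuit_score(f, c, r, e).values
            up = circuit_score(f + 0.5, c, r, e).values
            down = circuit_score(f, c, r, e + 0.5).values
            assert (up > base).all() and (down < base).all()
            bq = basq_score(f, c, r, e).values
            assert (basq_score(f + 0.5, c, r, e).values > bq).all()
            assert (basq_score(f, c, r + 0.5, e).values < bq).all()


class TestPercentileMap:
    def test_rank_definition(self):
        sv = ScoreVector(series([5.0, 1.0, 3.0]), "s", "IHC")
        assert list(percentile_map(sv).values) == [1.0, 0.0, 0.5]

    def test_all_equal_maps_to_half(self):
        sv = ScoreVector(series([2.0, 2.0, 2.0, 2.0]), "s", "IHC")
        assert list(percentile_map(sv).values) == [0.5] * 4

    def test_missing_preserved(self):
        sv = ScoreVector(series([np.nan, 4.0, 2.0]), "s", "mRNA")
        out = percentile_map(sv).values
        assert np.isnan(out.iloc[0]) and out.iloc[1] == 1.0 and out.iloc[2] == 0.0

    def test_all_missing_is_error(self):
        sv = ScoreVector(series([np.nan, np.nan]), "s", "mRNA")
        with pytest.raises(ValidationError):
            percentile_map(sv)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40, unique=True))
    def test_matches_sort_based_oracle_and_is_monotone(self, values):
        sv = ScoreVector(series(values), "s", "mRNA")
        out = percentile_map(sv).values.to_numpy()
        # oracle: sort and index
        order = np.argsort(values)
        expected = np.empty(len(values))
        expected[order] = np.arange(len(values)) / (len(values) - 1)
        assert np.allclose(out, expected)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestVarianceFilter:
    def test_keeps_highest_variance_matches_full_sort(self):
        # four genes with variances 0 < v1 < v2 < v3; oracle = full sort
        rows = [[5, 5, 5], [4, 5, 6], [3, 5, 7], [1, 5, 9]]
        em = make_expr(rows, genes=["A", "B", "C", "D"])
        out = variance_filter(em, 0.5)
        variances = em.values.var(axis=1, ddof=1)
        expected = set(variances.sort_values(ascending=False).index[:2])
        assert set(out.gene_ids) == expected == {"C", "D"}

    def test_fraction_one_is_identity(self):
        em = make_expr([[1, 2], [3, 4]])
        out = variance_filter(em, 1.0)
        pd.testing.assert_frame_equal(out.values, em.values)

    def test_gene_count_uses_ceiling(self):
        # 14 062 genes at fraction 0.5 must retain exactly 7 031
        n = 14062
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.normal(size=(n, 2)), index=[f"G{i:05d}" for i in range(n)],
            columns=["S1", "S2"],
        )
        out = variance_filter(make_expr(df.to_numpy(), genes=list(df.index)), 0.5)
        assert out.n_genes == 7031

    def test_retained_variance_dominates_dropped(self):
        rng = np.random.default_rng(2)
        em = make_expr(rng.normal(scale=rng.uniform(0.1, 3, size=(30, 1)), size=(30, 8)))
        out = variance_filter(em, 0.4)
        variances = em.values.var(axis=1, ddof=1)
        kept = variances.loc[out.gene_ids]
        dropped = variances.drop(out.gene_ids)
        assert kept.min() >= dropped.max()
        # submatrix: same sample set, genes subset in input order
        assert out.sample_ids == em.sample_ids
        assert set(out.gene_ids) <= set(em.gene_ids)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, fraction):
        em = make_expr([[1, 2]])
        with pytest.raises(ValidationError):
            variance_filter(em, fraction)
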