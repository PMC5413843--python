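import itertools

import numpy as np
import pandas as pd
import pytest

from phenoclass.consensus import (
    SplitParams,
    consensus_matrix,
    sequential_splits,
    two_way_split,
)
from phenoclass.types import ValidationError

from conftest import make_expr


def planted_groups(n_per_group, separation, n_genes=40, seed=0, n_groups=2):
    """Expression with ``n_groups`` mean-shifted sample groups."""
    rng = np.random.default_rng(seed)
    blocks = []
    for g in range(n_groups):
        means = np.zeros(n_genes)
        means[g * (n_genes // n_groups):(g + 1) * (n_genes // n_groups)] = separation
        blocks.append(rng.normal(means[:, None], 1.0, size=(n_genes, n_per_group)))
    X = np.concatenate(blocks, axis=1) + 6.0
    samples = [f"S{i:03d}" for i in range(n_per_group * n_groups)]
    labels = np.repeat(np.arange(n_groups), n_per_group)
    return make_expr(X, samples=samples), labels


class TestConsensusMatrix:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_symmetric_unit_diagonal_bounded(self, seed):
        expr, _ = planted_groups(6, 1.0, seed=seed)
        cm = consensus_matrix(expr, n_subsamples=30, seed=seed)
        arr = cm.values.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)
        assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_single_full_draw_is_comembership(self):
        expr, labels = planted_groups(4, 8.0)
        cm = consensus_matrix(expr, n_subsamples=1, sample_fraction=1.0, seed=0)
        arr = cm.values.to_numpy()
        assert set(np.unique(arr)) <= {0.0, 1.0}
        expected = (labels[:, None] == labels[None, :]).astype(float)
        assert np.array_equal(arr, expected)

    def test_well_separated_groups_give_binary_consensus(self):
        expr, labels = planted_groups(5, 10.0)
        cm = consensus_matrix(expr, n_subsamples=40, seed=3)
        arr = cm.values.to_numpy()
        within = arr[labels[:, None] == labels[None, :]]
        between = arr[labels[:, None] != labels[None, :]]
        assert np.allclose(within, 1.0)
        assert np.allclose(between, 0.0)

    def test_matches_bruteforce_recount_of_logged_partitions(self):
        expr, _ = planted_groups(4, 3.0, seed=5)  # n = 8
        cm, records = consensus_matrix(
            expr, n_subsamples=50, seed=7, return_records=True
        )
        ids = cm.sample_ids
        co_drawn = pd.DataFrame(0.0, index=ids, columns=ids)
        co_clust = pd.DataFrame(0.0, index=ids, columns=ids)
        for rec in records:
            for a, b in itertools.product(rec.sample_ids, repeat=2):
                co_drawn.loc[a, b] += 1
                if rec.labels[rec.sample_ids.index(a)] == rec.labels[rec.sample_ids.index(b)]:
                    co_clust.loc[a, b] += 1
        expected = (co_clust / co_drawn).fillna(0.0)
        np.fill_diagonal(expected.values, 1.0)
        pd.testing.assert_frame_equal(cm.values, expected)

    def test_constant_profile_error_with_pearson(self):
        expr = make_expr(np.ones((10, 4)))
        with pytest.raises(ValidationError, match="constant"):
            consensus_matrix(expr, n_subsamples=5, seed=0, distance="pearson")


class TestTwoWaySplit:
    def test_perfect_separation_has_stability_one(self):
        expr, labels = planted_groups(10, 10.0)
        res = two_way_split(expr, SplitParams(n_subsamples=40, min_leaf_size=5), seed=1)
        assert res.pac == 0.0 and res.stability == 1.0
        sides = {frozenset(res.left), frozenset(res.right)}
        samples = np.array(expr.sample_ids)
        expected = {frozenset(samples[labels == 0]), frozenset(samples[labels == 1])}
        assert sides == expected

    def test_pure_noise_has_low_stability(self):
        # the ambiguity statistic is assessed under the correlation metric,
        # where subsample partitions of unstructured data genuinely disagree
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            expr = make_expr(rng.normal(6, 0.5, size=(120, 80)))
            res = two_way_split(
                expr,
                SplitParams(n_subsamples=60, min_leaf_size=10, distance="pearson"),
                seed=seed,
            )
            assert res.stability < 0.35


class TestSequentialSplits:
    def test_single_planted_group_gives_single_leaf(self):
        for seed in range(3):
            rng = np.random.default_rng(300 + seed)
            expr = make_expr(rng.normal(6, 0.5, size=(120, 80)))
            tree = sequential_splits(
                expr,
                SplitParams(n_subsamples=60, min_leaf_size=10, distance="pearson"),
                seed=seed,
            )
            assert tree.n_leaves == 1

    def test_four_well_separated_groups_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        expr, labels = planted_groups(12, 8.0, n_genes=80, n_groups=4, seed=8)
        params = SplitParams(n_subsamples=40, min_leaf_size=6, stability_threshold=0.3)
        tree = sequential_splits(expr, params, seed=4)
        assert tree.n_leaves == 4
        assigned = tree.labels().labels.loc[expr.sample_ids]
        assert adjusted_rand_score(labels, assigned) == 1.0

    def test_seed_determinism(self):
        expr, _ = planted_groups(10, 2.0, n_genes=60, seed=9)
        params = SplitParams(n_subsamples=30, min_leaf_size=5)
        t1 = sequential_splits(expr, params, seed=5)
        t2 = sequential_splits(expr, params, seed=5)
        pd.testing.assert_series_equal(t1.labels().labels, t2.labels().labels)
        assert [round(n.stability, 12) for n in t1.internal_nodes()] == [
            round(n.stability, 12) for n in t2.internal_nodes()
        ]

    def test_permutation_equivariance(self):
        expr, _ = planted_groups(8, 4.0, n_genes=50, seed=10)
        params = SplitParams(n_subsamples=30, min_leaf_size=4)
        base = sequential_splits(expr, params, seed=6).labels().labels
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.sample_ids)
        shuffled = expr.select_samples(list(perm))
        permuted = sequential_splits(shuffled, params, seed=6).labels().labels
        pd.testing.assert_series_equal(
            base.sort_index(), permuted.sort_index(), check_names=False
        )

    def test_stability_increases_with_separation(self):
        separations = [0.0, 2.0, 8.0]
        medians = []
        for sep in separations:
            stabs = []
            for seed in range(3):
                expr, _ = planted_groups(10, sep, n_genes=60, seed=20 + seed)
                res = two_way_split(
                    expr, SplitParams(n_subsamples=40, min_leaf_size=5), seed=seed
                )
                stabs.append(res.stability)
            medians.append(float(np.median(stabs)))
        assert medians[0] <= medians[1] + 0.05
        assert medians[1] <= medians[2] + 0.05
        assert medians[2] > medians[0]
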