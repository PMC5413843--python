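"""Sample clustering by sequential two-way consensus splits.

Consensus clustering asks how often two samples land in the same cluster
when the clustering is repeated on random subsamples of the cohort.  Here
the inner clustering is average-linkage hierarchical clustering of sample
expression profiles cut into k = 2 groups.  The default profile distance is
Euclidean on log2 values: in admixed bulk profiles much of the cluster
signal is carried by coherent amplitude programmes (proliferation, stromal
and immune infiltration, tumour purity) that a scale-free correlation
distance is largely blind to; 1 - Pearson correlation remains available via
``distance="pearson"``.  The consensus value for a sample pair is

    (# subsamples where both were drawn and co-clustered) /
    (# subsamples where both were drawn),

with 0/0 defined as 0 and the diagonal fixed at 1.  A split is considered
stable when its consensus matrix is close to binary; the proportion of
ambiguous clustering (PAC) -- the fraction of off-diagonal consensus entries
strictly inside a window such as (0.1, 0.9) -- measures ambiguity, and
stability = 1 - PAC.  The cohort is partitioned by recursively applying
stable two-way splits, yielding a binary tree whose leaves are the final
consensus clusters.

All randomness is keyed to sample identity rather than column position:
sample ids are sorted lexicographically before any subsample is drawn, so
permuting the input columns permutes the output assignments identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .types import ExpressionMatrix, LabelTable, ValidationError

__all__ = [
    "ConsensusMatrix",
    "SubsampleRecord",
    "SplitParams",
    "SplitResult",
    "ClusterNode",
    "ClusterTree",
    "consensus_matrix",
    "two_way_split",
    "sequential_splits",
]


@dataclass(frozen=True)
class ConsensusMatrix:
    """Symmetric matrix of pairwise co-clustering frequencies in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        arr = df.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1] or not (df.index == df.columns).all():
            raise ValidationError("consensus matrix must be square with matching ids")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValidationError("consensus matrix must be symmetric")
        if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
            raise ValidationError("consensus entries must lie in [0, 1]")
        if not np.allclose(np.diag(arr), 1.0):
            raise ValidationError("consensus diagonal must be 1")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]


@dataclass(frozen=True)
class SubsampleRecord:
    """One subsample draw: which samples were drawn and their cluster labels."""

    sample_ids: tuple[str, ...]
    labels: tuple[int, ...]


@dataclass(frozen=True)
class SplitParams:
    """Parameters of a consensus two-way split and of the recursion stop rule.

    ``n_subsamples`` draws of ``sample_fraction`` of the samples feed the
    consensus matrix; a node is split only when the candidate split's
    stability (1 - PAC over ``pac_window``) reaches ``stability_threshold``,
    both resulting children hold at least ``min_leaf_size`` samples, and the
    node's depth is below ``max_depth``.  Requiring the minimum size of both
    children (rather than only of further recursion) keeps tight outlier
    subsets from being chipped off as micro-clusters.  Genes are never
    subsampled.
    """

    n_subsamples: int = 100
    sample_fraction: float = 0.8
    min_leaf_size: int = 25
    stability_threshold: float = 0.35
    max_depth: int = 6
    pac_window: tuple[float, float] = (0.1, 0.9)
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.n_subsamples < 1:
            raise ValidationError("n_subsamples must be >= 1")
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValidationError("sample_fraction must be in (0, 1]")
        lo, hi = self.pac_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError("pac_window must satisfy 0 <= lo < hi <= 1")
        if self.distance not in ("euclidean", "pearson"):
            raise ValidationError(f"unknown distance {self.distance!r}")


def _profile_distance(expr: ExpressionMatrix, distance: str = "euclidean") -> np.ndarray:
    """Pairwise distance between sample profiles.

    ``"euclidean"`` (default) acts on raw log2 values; ``"pearson"`` is
    1 - Pearson correlation, which requires non-constant profiles.
    """
    X = expr.values.to_numpy(dtype=float)  # genes x samples
    if distance == "euclidean":
        return squareform(pdist(X.T, metric="euclidean"))
    if distance != "pearson":
        raise ValidationError(f"unknown distance {distance!r}")
    stds = X.std(axis=0)
    if (stds == 0).any():
        sample = expr.sample_ids[int(np.argmax(stds == 0))]
        raise ValidationError(
            f"sample {sample!r} has a constant expression profile; "
            "correlation distance is undefined"
        )
    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def consensus_matrix(
    expr: ExpressionMatrix,
    k: int = 2,
    n_subsamples: int = 100,
    sample_fraction: float = 0.8,
    seed: int | np.random.SeedSequence | None = 0,
    return_records: bool = False,
    distance: str = "euclidean",
) -> ConsensusMatrix | tuple[ConsensusMatrix, tuple[SubsampleRecord, ...]]:
    """Consensus co-clustering frequencies over subsampled 2-way clusterings.

    Each of ``n_subsamples`` draws takes ``floor(sample_fraction * n)``
    samples without replacement, clusters them into ``k`` groups by
    average-linkage hierarchical clustering of sample profiles (``distance``
    is ``"euclidean"`` or ``"pearson"``), and counts co-clustering.
    Reproducible given ``seed``.  With ``return_records=True`` the
    individual subsample partitions are returned alongside the matrix (used
    for independent recounting).
    """
    n = expr.n_samples
    if n < 2 * k:
        raise ValidationError(f"need at least {2 * k} samples, got {n}")
    if not (0.0 < sample_fraction <= 1.0):
        raise ValidationError("sample_fraction must be in (0, 1]")
    if n_subsamples < 1:
        raise ValidationError("n_subsamples must be >= 1")
    order = sorted(expr.sample_ids)
    canon = expr.select_samples(order)
    dist = _profile_distance(canon, distance)
    m = int(np.floor(sample_fraction * n))
    if m < k:
        raise ValidationError(
            f"subsample size {m} is below the number of clusters {k}"
        )
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(seed)
    co_drawn = np.zeros((n, n))
    co_clustered = np.zeros((n, n))
    records: list[SubsampleRecord] = []
    for _ in range(n_subsamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = dist[np.ix_(idx, idx)]
        condensed = squareform(sub, checks=False)
        labels = fcluster(linkage(condensed, method="average"), t=k, criterion="maxclust")
        co_drawn[np.ix_(idx, idx)] += 1
        for lab in np.unique(labels):
            members = idx[labels == lab]
            co_clustered[np.ix_(members, members)] += 1
        if return_records:
            records.append(
                SubsampleRecord(
                    tuple(order[i] for i in idx), tuple(int(v) for v in labels)
                )
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = np.where(co_drawn > 0, co_clustered / np.maximum(co_drawn, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    # report in the caller's sample order
    df = pd.DataFrame(consensus, index=order, columns=order)
    df = df.loc[expr.sample_ids, expr.sample_ids]
    cm = ConsensusMatrix(df)
    if return_records:
        return cm, tuple(records)
    return cm


def _pac(consensus: np.ndarray, window: tuple[float, float]) -> float:
    lo, hi = window
    iu = np.triu_indices_from(consensus, k=1)
    off = consensus[iu]
    if off.size == 0:
        return 0.0
    return float(np.mean((off > lo) & (off < hi)))


@dataclass(frozen=True)
class SplitResult:
    """A two-way consensus split of a sample set."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    stability: float
    pac: float
    consensus: ConsensusMatrix


def _robust_two_cut(
    mat: np.ndarray, min_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two-way cut of the consensus dendrogram, robust to outlier branches.

    The average-linkage tree of (1 - consensus) is walked from the top; tiny
    branches (below ``min_size``) are peeled off until a cut with two
    adequately sized sides is found, and the peeled samples are then
    assigned to the side of higher mean consensus.  If no such cut exists
    (small inputs), the plain two-cluster cut is used.
    """
    n = mat.shape[0]
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    node = to_tree(Z)
    pooled: list[int] = []
    side_a: Optional[list[int]] = None
    side_b: Optional[list[int]] = None
    while not node.is_leaf():
        left, right = node.get_left(), node.get_right()
        if min(left.get_count(), right.get_count()) >= min_size:
            side_a = left.pre_order(lambda x: x.id)
            side_b = right.pre_order(lambda x: x.id)
            break
        smaller, bigger = sorted((left, right), key=lambda t: t.get_count())
        pooled.extend(smaller.pre_order(lambda x: x.id))
        node = bigger
    if side_a is None or side_b is None:
        labels = fcluster(Z, t=2, criterion="maxclust")
        side_a = list(np.flatnonzero(labels == labels[0]))
        side_b = [i for i in range(n) if i not in set(side_a)]
        pooled = []
    for i in pooled:
        mean_a = float(mat[i, side_a].mean())
        mean_b = float(mat[i, side_b].mean())
        (side_a if mean_a >= mean_b else side_b).append(i)
    mask = np.zeros(n, dtype=bool)
    mask[side_a] = True
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def two_way_split(
    expr: ExpressionMatrix,
    params: Optional[SplitParams] = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> SplitResult:
    """Split samples into two groups by consensus clustering.

    The final partition cuts an average-linkage tree of (1 - consensus) at
    two clusters (robust to outlier branches, see :func:`_robust_two_cut`);
    stability is 1 - PAC.  The ``left`` group is the one containing the
    lexicographically smallest sample id.
    """
    params = params or SplitParams()
    cm = consensus_matrix(
        expr,
        k=2,
        n_subsamples=params.n_subsamples,
        sample_fraction=params.sample_fraction,
        seed=seed,
        distance=params.distance,
    )
    order = sorted(cm.sample_ids)
    mat = cm.values.loc[order, order].to_numpy(dtype=float)
    idx_a, idx_b = _robust_two_cut(mat, params.min_leaf_size)
    g1 = [order[i] for i in idx_a]
    g2 = [order[i] for i in idx_b]
    if not g2:
        left, right = tuple(g1), ()
    elif min(g1) <= min(g2):
        left, right = tuple(g1), tuple(g2)
    else:
        left, right = tuple(g2), tuple(g1)
    pac = _pac(mat, params.pac_window)
    return SplitResult(left, right, stability=1.0 - pac, pac=pac, consensus=cm)


@dataclass
class ClusterNode:
    """A node of the sequential-split tree."""

    sample_ids: tuple[str, ...]
    depth: int
    stability: Optional[float] = None
    pac: Optional[float] = None
    consensus: Optional[ConsensusMatrix] = None
    children: Optional[tuple["ClusterNode", "ClusterNode"]] = None
    leaf_label: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def to_dict(self, include_samples: bool = True) -> dict:
        d: dict = {
            "n_samples": len(self.sample_ids),
            "depth": self.depth,
            "stability": self.stability,
            "pac": self.pac,
        }
        if self.is_leaf:
            d["leaf_label"] = self.leaf_label
            if include_samples:
                d["sample_ids"] = list(self.sample_ids)
        else:
            d["children"] = [c.to_dict(include_samples) for c in self.children]
        return d


@dataclass
class ClusterTree:
    """Binary tree of sequential two-way consensus splits."""

    root: ClusterNode

    def leaves(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for child in node.children:
                    walk(child)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def labels(self) -> LabelTable:
        """Per-sample leaf assignment as a LabelTable."""
        mapping: dict[str, str] = {}
        vocab: list[str] = []
        for leaf in self.leaves():
            vocab.append(leaf.leaf_label)
            for s in leaf.sample_ids:
                mapping[s] = leaf.leaf_label
        series = pd.Series(mapping, name="cluster").loc[sorted(mapping)]
        return LabelTable(series, vocabulary=tuple(vocab))

    def to_dict(self, include_samples: bool = True) -> dict:
        return {"n_leaves": self.n_leaves, "tree": self.root.to_dict(include_samples)}


def sequential_splits(
    expr: ExpressionMatrix,
    params: Optional[SplitParams] = None,
    seed: int = 0,
) -> ClusterTree:
    """Recursively partition samples by stable two-way consensus splits.

    The input is expected to be variance-filtered already; the gene set is
    global and is not re-filtered within children.  A node becomes a leaf
    when it is too small, too deep, or its candidate split is not stable.
    Leaves are labelled ``C1, C2, ...`` in post-order.
    """
    params = params or SplitParams()
    root_ss = np.random.SeedSequence(seed)

    def grow(sample_ids: tuple[str, ...], depth: int, ss: np.random.SeedSequence) -> ClusterNode:
        node = ClusterNode(sample_ids=sample_ids, depth=depth)
        n = len(sample_ids)
        if depth >= params.max_depth or n < max(4, 2 * params.min_leaf_size):
            return node
        sub = expr.select_samples(sorted(sample_ids))
        own_ss, left_ss, right_ss = ss.spawn(3)
        split = two_way_split(sub, params, seed=own_ss)
        node.stability = split.stability
        node.pac = split.pac
        node.consensus = split.consensus
        if (
            split.stability < params.stability_threshold
            or len(split.left) < params.min_leaf_size
            or len(split.right) < params.min_leaf_size
        ):
            return node
        node.children = (
            grow(split.left, depth + 1, left_ss),
            grow(split.right, depth + 1, right_ss),
        )
        return node

    root = grow(tuple(sorted(expr.sample_ids)), 0, root_ss)
    counter = 0

    def label(node: ClusterNode) -> None:
        nonlocal counter
        if node.is_leaf:
            counter += 1
            node.leaf_label = f"C{counter}"
        else:
            for child in node.children:
                label(child)

    label(root)
    return ClusterTree(root)
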