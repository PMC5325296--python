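"""Beta diversity: similarity matrices, UPGMA clustering, SIMPROF tests.

Three compositional similarity indices on a percent scale (0 = disjoint,
100 = identical):

* Jaccard — presence/absence only, ``100 a / (a + b + c)`` with *a*
  shared species and *b*, *c* unique to either site;
* quantitative Sorensen (Bray–Curtis similarity) — abundance-weighted,
  ``100 * 2 W / (X + Y)`` with ``W = sum_i min(x_i, y_i)``;
* Morisita–Horn — dominance-weighted and invariant to proportional
  rescaling of either assemblage.

Sites are clustered by UPGMA on the similarity matrix (merging at
decreasing similarity), and cluster structure is tested top-down with
Type-1 SIMPROF: at each dendrogram node the statistic pi is the summed
absolute deviation of the ordered within-group similarity profile from
its permutation-null mean profile, with species shuffled independently
across the node's sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import CommunityMatrix, ValidationError

__all__ = [
    "similarity_matrix",
    "SimilarityMatrix",
    "upgma",
    "Dendrogram",
    "DendroNode",
    "simprof",
    "SimprofResult",
    "SIMILARITY_INDICES",
]


def _jaccard(x: np.ndarray, y: np.ndarray) -> float:
    px, py = x > 0, y > 0
    a = np.sum(px & py)
    union = np.sum(px | py)
    return 100.0 * a / union if union else 100.0


def _sorensen_quantitative(x: np.ndarray, y: np.ndarray) -> float:
    total = x.sum() + y.sum()
    return 100.0 * 2.0 * np.minimum(x, y).sum() / total if total else 100.0


def _sorensen_incidence(x: np.ndarray, y: np.ndarray) -> float:
    px, py = x > 0, y > 0
    a = np.sum(px & py)
    denom = px.sum() + py.sum()
    return 100.0 * 2.0 * a / denom if denom else 100.0


def _morisita_horn(x: np.ndarray, y: np.ndarray) -> float:
    X, Y = float(x.sum()), float(y.sum())
    if X == 0 or Y == 0:
        return float("nan")
    num = 2.0 * float(x @ y)
    if num == 0.0:
        return 0.0
    lam = float(x @ x) / X**2 + float(y @ y) / Y**2
    return 100.0 * num / (lam * X * Y)


SIMILARITY_INDICES: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "jaccard": _jaccard,
    "sorensen_quantitative": _sorensen_quantitative,
    "sorensen_incidence": _sorensen_incidence,
    "morisita_horn": _morisita_horn,
}

#: The index family mirrors diversity orders: Jaccard pairs with order-0
#: (richness) beta diversity, quantitative Sorensen with order 1, and
#: Morisita-Horn with order 2.  Recorded as metadata only; no numeric
#: conversion between similarity and beta diversity is performed.
INDEX_DIVERSITY_ORDER: dict[str, int] = {
    "jaccard": 0,
    "sorensen_quantitative": 1,
    "morisita_horn": 2,
}


@dataclass
class SimilarityMatrix:
    """Symmetric site-by-site similarity in percent, diagonal fixed at 100."""

    values: pd.DataFrame
    index_name: str

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise ValidationError("similarity matrix must be symmetric")
        if np.nanmin(arr) < -1e-9 or np.nanmax(arr) > 100 + 1e-9:
            raise ValidationError("similarities must lie in [0, 100]")
        np.fill_diagonal(arr, 100.0)
        self.values = pd.DataFrame(arr, index=self.values.index, columns=self.values.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        """Upper-triangle similarities in row-major pair order."""
        arr = self.values.to_numpy()
        iu = np.triu_indices(arr.shape[0], k=1)
        return arr[iu]


def _pairwise(counts: np.ndarray, index: str) -> np.ndarray:
    fn = SIMILARITY_INDICES[index]
    n = counts.shape[0]
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(counts[i], counts[j])
    return out


def similarity_matrix(m: CommunityMatrix, index: str = "sorensen_quantitative") -> SimilarityMatrix:
    """Pairwise compositional similarity between all sites under one index."""
    if index not in SIMILARITY_INDICES:
        raise ValueError(f"unknown index {index!r}; choose from {sorted(SIMILARITY_INDICES)}")
    totals = m.site_totals()
    empty = totals[totals == 0]
    if len(empty):
        raise ValidationError(f"similarity undefined for empty sites: {list(empty.index)}")
    arr = _pairwise(m.counts.to_numpy(dtype=float), index)
    return SimilarityMatrix(pd.DataFrame(arr, index=m.site_ids, columns=m.site_ids), index)


# ---------------------------------------------------------------------------
# UPGMA on similarities


@dataclass
class DendroNode:
    """A merge node (or leaf) of the UPGMA tree, on the similarity scale."""

    leaves: tuple[int, ...]
    height: float  # similarity at which the children merged; 100 at leaves
    children: tuple["DendroNode", "DendroNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class Dendrogram:
    root: DendroNode
    site_ids: list[str]
    index_name: str = ""

    def merge_heights(self) -> list[float]:
        """Internal-node similarities from root downward (non-decreasing)."""
        out: list[float] = []

        def walk(node: DendroNode) -> None:
            if not node.is_leaf:
                out.append(node.height)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def cut(self, similarity: float) -> list[tuple[str, ...]]:
        """Clusters obtained by cutting all merges below the given similarity."""
        blocks: list[tuple[str, ...]] = []

        def walk(node: DendroNode) -> None:
            if node.is_leaf or node.height >= similarity:
                blocks.append(tuple(self.site_ids[i] for i in sorted(node.leaves)))
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return blocks

    def to_newick(self) -> str:
        """Newick string with branch lengths (100 - similarity) / 2.

        The tree is ultrametric on the distance scale: a node merging at
        similarity s sits at height (100 - s)/2, and each branch length is
        the parent/child height difference.
        """

        def depth(node: DendroNode) -> float:
            return (100.0 - node.height) / 2.0 if not node.is_leaf else 0.0

        def fmt(node: DendroNode, parent_depth: float) -> str:
            bl = parent_depth - depth(node)
            if node.is_leaf:
                return f"{self.site_ids[node.leaves[0]]}:{bl:.6g}"
            inner = ",".join(fmt(c, depth(node)) for c in node.children)
            return f"({inner}):{bl:.6g}"

        root_depth = depth(self.root)
        inner = ",".join(fmt(c, root_depth) for c in self.root.children)
        return f"({inner});"


def upgma(s: SimilarityMatrix) -> Dendrogram:
    """Average-linkage clustering on similarities.

    Repeatedly merges the most similar pair of clusters; the similarity
    between clusters is the arithmetic mean of all member pairwise
    similarities (size-weighted update).  Ties are broken by the
    lexicographically smallest pair of sorted leaf-index tuples, so
    dendrograms are reproducible.
    """
    arr = s.values.to_numpy(dtype=float).copy()
    n = arr.shape[0]
    nodes: list[DendroNode] = [DendroNode((i,), 100.0) for i in range(n)]
    sizes = [1] * n
    active = list(range(n))
    sim = {(i, j): arr[i, j] for i in range(n) for j in range(i + 1, n)}

    def key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    while len(active) > 1:
        best = None
        for a_idx, i in enumerate(active):
            for j in active[a_idx + 1 :]:
                pair = tuple(sorted((nodes[i].leaves, nodes[j].leaves)))
                cand = (-sim[key(i, j)], pair)
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        _, i, j = best
        h = sim[key(i, j)]
        left, right = sorted((nodes[i], nodes[j]), key=lambda nd: nd.leaves)
        merged = DendroNode(
            tuple(sorted(nodes[i].leaves + nodes[j].leaves)),
            h,
            (left, right),
        )
        new_size = sizes[i] + sizes[j]
        nodes.append(merged)
        sizes.append(new_size)
        new_idx = len(nodes) - 1
        active = [k for k in active if k not in (i, j)]
        for k in active:
            sim[key(new_idx, k)] = (
                sizes[i] * sim[key(i, k)] + sizes[j] * sim[key(j, k)]
            ) / new_size
        active.append(new_idx)

    return Dendrogram(nodes[active[0]], s.site_ids, s.index_name)


# ---------------------------------------------------------------------------
# SIMPROF


@dataclass
class SimprofNodeTest:
    leaves: tuple[str, ...]
    height: float
    pi_stat: float
    p_value: float
    rejected: bool


@dataclass
class SimprofResult:
    """Outcome of the top-down SIMPROF recursion on a UPGMA tree.

    ``partition`` lists the maximal homogeneous site groups (nodes where
    the null of no internal structure was not rejected, or leaves).
    """

    tests: list[SimprofNodeTest]
    partition: list[tuple[str, ...]]
    index_name: str
    alpha: float
    n_perm_mean: int
    n_perm_null: int
    seed: int

    @property
    def n_significant(self) -> int:
        return sum(t.rejected for t in self.tests)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node": "|".join(t.leaves),
                    "n_sites": len(t.leaves),
                    "height_similarity": t.height,
                    "pi": t.pi_stat,
                    "p": t.p_value,
                    "decision": "reject" if t.rejected else "stop",
                }
                for t in self.tests
            ]
        )


def _profile(counts: np.ndarray, index: str) -> np.ndarray:
    arr = _pairwise(counts, index)
    iu = np.triu_indices(arr.shape[0], k=1)
    return np.sort(arr[iu])


def _permute_species(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle each species' counts independently across sites."""
    idx = rng.random(counts.shape).argsort(axis=0)
    return counts[idx, np.arange(counts.shape[1])]


def simprof_test(
    counts: np.ndarray,
    index: str,
    n_perm_mean: int,
    n_perm_null: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One SIMPROF test on a site-block: returns (pi, P).

    pi = sum_k |s_(k) - sbar_(k)| where s_(k) is the ordered observed
    similarity profile and sbar_(k) the mean ordered profile over
    ``n_perm_mean`` species-wise permutations; P compares pi against
    ``n_perm_null`` further permuted profiles, with the +1 correction so
    P is never 0.
    """
    obs = _profile(counts, index)
    mean_prof = np.zeros_like(obs)
    for _ in range(n_perm_mean):
        mean_prof += _profile(_permute_species(counts, rng), index)
    mean_prof /= n_perm_mean
    pi_obs = float(np.abs(obs - mean_prof).sum())
    exceed = 0
    for _ in range(n_perm_null):
        pi_b = float(np.abs(_profile(_permute_species(counts, rng), index) - mean_prof).sum())
        if pi_b >= pi_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm_null + 1)
    return pi_obs, p


def simprof(
    m: CommunityMatrix,
    index: str = "sorensen_quantitative",
    alpha: float = 0.05,
    n_perm_mean: int = 1000,
    n_perm_null: int = 999,
    seed: int = 0,
) -> SimprofResult:
    """Type-1 SIMPROF applied top-down on the UPGMA tree.

    The root node is tested first; where the null (sites exchangeable,
    species shuffled independently) is rejected at ``alpha``, the
    recursion descends into both children.  Nodes with fewer than three
    leaves are not testable and terminate the recursion.
    """
    if m.n_sites < 3:
        raise ValidationError("SIMPROF needs at least 3 sites")
    s = similarity_matrix(m, index)
    tree = upgma(s)
    counts_all = m.counts.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    tests: list[SimprofNodeTest] = []
    partition: list[tuple[str, ...]] = []

    def walk(node: DendroNode) -> None:
        labels = tuple(m.site_ids[i] for i in sorted(node.leaves))
        if node.is_leaf or len(node.leaves) < 3:
            partition.append(labels)
            return
        block = counts_all[list(sorted(node.leaves))]
        pi, p = simprof_test(block, index, n_perm_mean, n_perm_null, rng)
        rejected = p <= alpha
        tests.append(SimprofNodeTest(labels, node.height, pi, p, rejected))
        if rejected:
            for c in node.children:
                walk(c)
        else:
            partition.append(labels)

    walk(tree.root)
    # merge two-leaf blocks that arose purely from untestable nodes: they
    # are their own partition blocks by construction
    return SimprofResult(
        tests=tests,
        partition=partition,
        index_name=index,
        alpha=alpha,
        n_perm_mean=n_perm_mean,
        n_perm_null=n_perm_null,
        seed=seed,
    )
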