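"""UPGMA dendrograms on band presence/absence, with Newick export.

The distance between two lanes is 100 − % similarity of their band
patterns (Dice by default, as in the rest of the package).  Clustering
is the unweighted pair-group method with arithmetic mean: repeatedly
merge the closest pair of clusters, defining the distance from the
merged cluster to any other as the size-weighted mean of its members'
distances.  Merge heights are half the merge distance, giving the usual
ultrametric dendrogram (all leaves equidistant from the root).  Ties are
broken by the lexicographically smallest cluster-id pair, so identical
inputs always give identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity import pairwise_similarity
from .model_io import BandMatrix

__all__ = ["Tree", "distance_matrix", "upgma", "to_newick"]


@dataclass(frozen=True)
class Tree:
    """Ultrametric merge tree.

    Leaves are numbered 0..n−1 in ``leaves`` order; merge k creates
    cluster id n+k.  Each merge is (id_a, id_b, height) with heights
    non-decreasing.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("a tree over n leaves needs n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def heights(self) -> dict[int, float]:
        """Height of every cluster id (leaves at 0)."""
        h = {i: 0.0 for i in range(self.n_leaves)}
        for k, (_, _, height) in enumerate(self.merges):
            h[self.n_leaves + k] = height
        return h

    def cophenetic(self) -> np.ndarray:
        """Leaf × leaf cophenetic distance matrix (2 × merge height of the
        lowest common cluster)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        d = np.zeros((n, n))
        for k, (a, b, height) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    d[i, j] = d[j, i] = 2.0 * height
            members[n + k] = members.pop(a) + members.pop(b)
        return d


def distance_matrix(bm: BandMatrix, method: str = "dice") -> tuple[np.ndarray, list[str]]:
    """Lane × lane distances d = 100 − % similarity on band presence."""
    n = len(bm.lane_ids)
    if n < 2:
        raise ValueError("distance matrix needs >= 2 lanes")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 100.0 - pairwise_similarity(
                bm.presence[i], bm.presence[j], method=method
            )
    return d, list(bm.lane_ids)


def upgma(d: np.ndarray, labels: list[str]) -> Tree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    ``d`` must be square, symmetric, non-negative, with zero diagonal.
    Merge height = merge distance / 2.  Ties broken by smallest (id_a,
    id_b) pair.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape must match labels")
    if n < 1:
        raise ValueError("need at least one leaf")
    if np.any(d < 0) or np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distances must be non-negative with zero diagonal")
    if not np.allclose(d, d.T, atol=1e-9, rtol=0):
        raise ValueError("distance matrix must be symmetric")

    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                dij = dist[(i, j)]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        dij, a, b = best
        merges.append((a, b, dij / 2.0))
        for c in active:
            if c in (a, b):
                continue
            dac = dist[tuple(sorted((a, c)))]
            dbc = dist[tuple(sorted((b, c)))]
            dnew = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            dist[(c, next_id) if c < next_id else (next_id, c)] = dnew
        size[next_id] = size[a] + size[b]
        active.discard(a)
        active.discard(b)
        active.add(next_id)
        next_id += 1
    return Tree(leaves=tuple(labels), merges=tuple(merges))


def to_newick(tree: Tree) -> str:
    """Serialize as Newick with branch lengths, so every root-to-leaf path
    length equals the final merge height."""
    n = tree.n_leaves
    if n == 1:
        return f"{tree.leaves[0]}:0;"
    heights = tree.heights()
    children: dict[int, tuple[int, int]] = {
        n + k: (a, b) for k, (a, b, _) in enumerate(tree.merges)
    }

    def min_leaf(node: int) -> int:
        if node < n:
            return node
        return min(min_leaf(c) for c in children[node])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            return f"{tree.leaves[node]}:{length:.12g}"
        a, b = sorted(children[node], key=min_leaf)
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{length:.12g}"

    root = n + len(tree.merges) - 1
    a, b = sorted(children[root], key=min_leaf)
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"
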