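"""Vietoris-Rips persistent homology for small point clouds.

Computes persistence pairs of the Rips filtration in homology dimensions
0 and 1:

* H0 by Kruskal-style union-find over edges in filtration order — deaths
  are the minimum-spanning-tree edge lengths, plus one essential class.
* H1 by GF(2) boundary-matrix reduction of the triangle columns over the
  edge basis, with columns represented as Python big-integer bitmasks
  (symmetric difference = XOR, pivot = highest set bit).

By default the filtration is truncated at the enclosing radius
``min_i max_j d(i, j)``, at which the complex is a cone, so every
1-dimensional class has died and truncation loses nothing; this is the
standard trick that keeps the triangle count manageable.  Complexity is
O(n^3) triangles, intended for clouds of at most a few hundred points;
callers embed larger series and subsample first (see
``representations.sliding_window_embed`` / ``farthest_point_subsample``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["PersistenceDiagram", "rips_persistence"]


@dataclass
class PersistenceDiagram:
    """Birth/death pairs per homology dimension.

    ``points[d]`` is an [n x 2] array of finite (birth, death) pairs;
    ``essential[d]`` is a 1-D array of birth times of classes that never
    die within the filtration.
    """

    points: dict = field(default_factory=dict)
    essential: dict = field(default_factory=dict)
    max_dim: int = 1

    def finite(self, dim: int) -> np.ndarray:
        return self.points.get(dim, np.zeros((0, 2)))

    def n_points(self, dim: int) -> int:
        return len(self.finite(dim))


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def rips_persistence(
    cloud: np.ndarray, max_dim: int = 1, threshold: float | None = None
) -> PersistenceDiagram:
    """Persistence diagram of the Rips filtration of ``cloud`` [P x m].

    ``threshold`` truncates the filtration; ``None`` uses the enclosing
    radius (exact for H0 and H1).  ``max_dim`` is 0 or 1.
    """
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    n = cloud.shape[0]
    if n == 0:
        raise ValueError("point cloud must contain at least one point")
    if max_dim not in (0, 1):
        raise ValueError("max_dim must be 0 or 1")
    pd_out = PersistenceDiagram(max_dim=max_dim)
    if n == 1:
        pd_out.points[0] = np.zeros((0, 2))
        pd_out.essential[0] = np.array([0.0])
        if max_dim >= 1:
            pd_out.points[1] = np.zeros((0, 2))
            pd_out.essential[1] = np.array([])
        return pd_out

    dmat = squareform(pdist(cloud))
    if threshold is None:
        threshold = float(dmat.max(axis=1).min())  # enclosing radius

    # --- edges in filtration order --------------------------------------
    iu, ju = np.triu_indices(n, k=1)
    lengths = dmat[iu, ju]
    order = np.lexsort((ju, iu, lengths))
    iu, ju, lengths = iu[order], ju[order], lengths[order]

    # --- H0: union-find over sorted edges --------------------------------
    uf = _UnionFind(n)
    h0_deaths = []
    creator_edges = []  # (edge_rank, length) of cycle-creating edges
    n_kept = 0
    for rank in range(len(lengths)):
        if lengths[rank] > threshold:
            break
        n_kept += 1
        if uf.union(int(iu[rank]), int(ju[rank])):
            h0_deaths.append(lengths[rank])
        else:
            creator_edges.append(rank)
    # components never merged within threshold are essential in H0
    n_components = len({uf.find(i) for i in range(n)})
    pd_out.points[0] = np.column_stack(
        [np.zeros(len(h0_deaths)), np.array(h0_deaths)]
    )
    pd_out.essential[0] = np.zeros(n_components)
    if max_dim == 0:
        return pd_out

    # --- H1: reduce triangle columns over the edge basis ------------------
    edge_rank = {}
    for rank in range(n_kept):
        edge_rank[(int(iu[rank]), int(ju[rank]))] = rank

    # a triangle enters the filtration with its last edge (highest rank),
    # so enumerate triangles attributed to their maximal-rank edge: this
    # counts each exactly once and handles length ties exactly
    tri = []
    for rank in range(n_kept):
        a, b = int(iu[rank]), int(ju[rank])
        for c in range(n):
            if c == a or c == b:
                continue
            r1 = edge_rank.get((min(a, c), max(a, c)))
            r2 = edge_rank.get((min(b, c), max(b, c)))
            if r1 is None or r2 is None:
                continue
            if rank > r1 and rank > r2:
                tri.append((lengths[rank], rank, r1, r2))
    tri.sort()

    low_to_col: dict[int, int] = {}
    col_values: list[float] = []
    columns: list[int] = []
    pairs = []
    for value, r0, r1, r2 in tri:
        col = (1 << r0) | (1 << r1) | (1 << r2)
        while col:
            low = col.bit_length() - 1
            holder = low_to_col.get(low)
            if holder is None:
                low_to_col[low] = len(columns)
                columns.append(col)
                col_values.append(value)
                birth = lengths[low]
                if value > birth:
                    pairs.append((birth, value))
                break
            col ^= columns[holder]

    paired_lows = set(low_to_col.keys())
    essential1 = [
        lengths[r] for r in creator_edges if r not in paired_lows
    ]
    pd_out.points[1] = (
        np.array(pairs) if pairs else np.zeros((0, 2))
    )
    pd_out.essential[1] = np.array(sorted(essential1))
    return pd_out
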