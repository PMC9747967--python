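"""Density-based clustering of cytokine-positive spots on the Visium hex grid.

The Visium array addresses spots by ``(array_row, array_col)`` with
``row + col`` always even; the six physical neighbours of a spot sit at
offsets ``(±1, ±1)`` and ``(0, ±2)`` in this index space.  All geometry here
operates directly on these integer indices.

Clustering proceeds in three steps:

1. cytokine-positive spots of one sample are linked whenever their Euclidean
   index-space distance is at most 2.0 (:func:`build_adjacency`);
2. connected components of that graph become cluster seeds
   (:func:`seed_clusters`);
3. each component is expanded by the radius-``r`` hex neighbourhood of its
   seeds, restricted to a spot universe, and overlapping clusters are merged
   transitively (:func:`expand_and_merge`).

Note that the distance-2.0 rule also links spots at offset ``(±2, 0)`` —
two array rows apart vertically — which are *not* physical hex neighbours.
This index-space rule is the default; pass ``strict_hex=True`` to restrict
adjacency to the six physical neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

__all__ = [
    "HexCoord",
    "DensityCluster",
    "hex_offsets",
    "hex_neighborhood",
    "hex_ball_size",
    "build_adjacency",
    "seed_clusters",
    "expand_and_merge",
    "cluster_readout",
]

HexCoord = tuple[int, int]

#: Euclidean index-space distance under which two cytokine+ spots are linked.
ADJACENCY_MAX_DISTANCE = 2.0

#: Offsets of the six physical hex neighbours in (row, col) index space.
STRICT_HEX_OFFSETS = frozenset(
    [(1, 1), (1, -1), (-1, 1), (-1, -1), (0, 2), (0, -2)]
)


def hex_ball_size(r: int) -> int:
    """Spot count of a radius-``r`` hex neighbourhood: the centered
    hexagonal number ``3r² + 3r + 1``."""
    return 3 * r * r + 3 * r + 1


@lru_cache(maxsize=32)
def hex_offsets(r: int) -> frozenset[HexCoord]:
    """Offsets ``(Δrow, Δcol)`` of the radius-``r`` hex neighbourhood.

    A spot at row offset ``j`` and column offset ``i`` belongs to the
    neighbourhood when ``|j| <= r``, ``|i| <= 2r - |j|`` and ``i + j`` is
    even (the array parity constraint).  The center ``(0, 0)`` is included;
    the set has exactly ``3r² + 3r + 1`` members.
    """
    if r < 0:
        raise ValueError(f"radius must be >= 0, got {r}")
    offs = set()
    for j in range(-r, r + 1):
        span = 2 * r - abs(j)
        for i in range(-span, span + 1):
            if (i + j) % 2 == 0:
                offs.add((j, i))
    return frozenset(offs)


def hex_neighborhood(center: HexCoord, r: int) -> set[HexCoord]:
    """All grid coordinates within hex radius ``r`` of ``center``
    (``center`` included).

    ``center`` must satisfy the parity invariant ``row + col`` even.
    """
    row, col = center
    if (row + col) % 2 != 0:
        raise ValueError(f"invalid hex coordinate {center}: row+col must be even")
    return {(row + dj, col + di) for dj, di in hex_offsets(r)}


@dataclass
class CytokineGraph:
    """Adjacency of cytokine-positive spots of one sample.

    ``nodes`` are indices into the coordinate array ``coords``; ``edges``
    are undirected index pairs with Euclidean index-space distance below
    the linking threshold.
    """

    coords: np.ndarray  # (n, 2) int array of (row, col)
    edges: list[tuple[int, int]]
    umis: np.ndarray | None = None  # cytokine UMI per node, optional

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


def build_adjacency(
    coords: Sequence[HexCoord] | np.ndarray,
    umis: Sequence[int] | np.ndarray | None = None,
    max_distance: float = ADJACENCY_MAX_DISTANCE,
    strict_hex: bool = False,
) -> CytokineGraph:
    """Link cytokine-positive spots within ``max_distance`` (inclusive)
    in Euclidean index space.

    Uses a KD-tree for the fixed-radius search; the result is identical to
    all-pairs thresholding.  With ``strict_hex=True`` only the six physical
    hex-neighbour offsets are kept.
    """
    coords = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
    if umis is not None:
        umis = np.asarray(umis)
        if len(umis) != len(coords):
            raise ValueError("umis length must match coords")
    if len(coords) == 0:
        return CytokineGraph(coords=coords, edges=[], umis=umis)
    tree = cKDTree(coords.astype(float))
    pairs = tree.query_pairs(r=max_distance, output_type="ndarray")
    edges: list[tuple[int, int]] = []
    for a, b in pairs:
        a, b = int(a), int(b)
        if strict_hex:
            d = (coords[b, 0] - coords[a, 0], coords[b, 1] - coords[a, 1])
            if d not in STRICT_HEX_OFFSETS:
                continue
        edges.append((a, b) if a < b else (b, a))
    edges.sort()
    return CytokineGraph(coords=coords, edges=edges, umis=umis)


def seed_clusters(graph: CytokineGraph) -> list[list[int]]:
    """Connected components of the cytokine graph, as sorted node-index
    lists.  Isolated cytokine+ spots form singleton components.

    Components are returned sorted by their smallest (row, col) coordinate,
    giving a deterministic order.
    """
    n = graph.n_nodes
    if n == 0:
        return []
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in graph.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = [sorted(c) for c in comps.values()]
    out.sort(key=lambda c: min(tuple(graph.coords[i]) for i in c))
    return out


@dataclass
class DensityCluster:
    """A merged cluster: cytokine+ seed spots plus their radius-``r``
    neighbourhood ring, with count sums read out from the raw matrix."""

    cluster_id: str
    sample_id: str
    radius: int
    seed_spots: frozenset[HexCoord]
    ring_spots: frozenset[HexCoord]
    cytokine_count: float = 0.0
    responder_count: float = 0.0
    weight: float = 0.0

    @property
    def member_spots(self) -> frozenset[HexCoord]:
        return self.seed_spots | self.ring_spots

    @property
    def n_seed_spots(self) -> int:
        return len(self.seed_spots)

    @property
    def n_ring_spots(self) -> int:
        return len(self.ring_spots)


def expand_and_merge(
    components: list[list[int]],
    graph: CytokineGraph,
    r: int,
    universe: Iterable[HexCoord],
    sample_id: str = "",
) -> list[DensityCluster]:
    """Expand seed components by their radius-``r`` hex neighbourhoods and
    merge overlapping clusters transitively until a fixpoint.

    The expansion of a component is the union of ``hex_neighborhood(seed, r)``
    over its seeds, intersected with ``universe`` (plus the seeds
    themselves).  Two expanded clusters sharing any member spot are merged;
    merging is independent of processing order.  Cluster ids are derived
    from the lexicographically smallest member coordinate.
    """
    if r < 0:
        raise ValueError(f"radius must be >= 0, got {r}")
    universe = set(universe)
    if not components:
        return []

    seed_sets: list[set[HexCoord]] = []
    member_sets: list[set[HexCoord]] = []
    for comp in components:
        seeds = {(int(graph.coords[i, 0]), int(graph.coords[i, 1])) for i in comp}
        members = set()
        for s in seeds:
            members |= hex_neighborhood(s, r)
        members &= universe
        members |= seeds  # seeds always belong, even if outside the universe
        seed_sets.append(seeds)
        member_sets.append(members)

    # transitive merge via union-find keyed by shared member spots
    parent = list(range(len(components)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    owner: dict[HexCoord, int] = {}
    for ci, members in enumerate(member_sets):
        for spot in members:
            if spot in owner:
                ra, rb = find(owner[spot]), find(ci)
                if ra != rb:
                    parent[rb] = ra
            else:
                owner[spot] = ci

    merged_seeds: dict[int, set[HexCoord]] = {}
    merged_members: dict[int, set[HexCoord]] = {}
    for ci in range(len(components)):
        root = find(ci)
        merged_seeds.setdefault(root, set()).update(seed_sets[ci])
        merged_members.setdefault(root, set()).update(member_sets[ci])

    clusters = []
    for root in merged_seeds:
        seeds = frozenset(merged_seeds[root])
        members = merged_members[root]
        ring = frozenset(members - seeds)
        anchor = min(members)
        cid = f"{sample_id}:{anchor[0]}_{anchor[1]}:r{r}" if sample_id else f"{anchor[0]}_{anchor[1]}:r{r}"
        clusters.append(
            DensityCluster(
                cluster_id=cid,
                sample_id=sample_id,
                radius=r,
                seed_spots=seeds,
                ring_spots=ring,
            )
        )
    clusters.sort(key=lambda c: min(c.member_spots))
    return clusters


def cluster_readout(
    cluster: DensityCluster,
    coord_to_spot: dict[HexCoord, int],
    counts: csr_matrix,
    cytokine_col: int,
    responder_cols: Sequence[int],
) -> DensityCluster:
    """Read out per-cluster sums from the raw count matrix.

    ``cytokine_count`` sums cytokine UMIs over seed spots only;
    ``responder_count`` sums raw UMIs of the responder signature genes over
    all member spots (seeds and ring); ``weight`` equals the cytokine count
    and later weights the cluster in the correlation.

    ``coord_to_spot`` maps (row, col) to a row index of ``counts`` for the
    cluster's sample; member coordinates missing from the map (e.g. grid
    positions without a spot) contribute nothing.
    """
    seed_rows = [coord_to_spot[c] for c in cluster.seed_spots if c in coord_to_spot]
    member_rows = [
        coord_to_spot[c] for c in cluster.member_spots if c in coord_to_spot
    ]
    cyt = float(counts[seed_rows, :][:, [cytokine_col]].sum()) if seed_rows else 0.0
    if member_rows and len(responder_cols) > 0:
        resp = float(counts[member_rows, :][:, list(responder_cols)].sum())
    else:
        resp = 0.0
    cluster.cytokine_count = cyt
    cluster.responder_count = resp
    cluster.weight = cyt
    return cluster
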