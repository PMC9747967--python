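"""Unit and property tests for hex-grid geometry and density clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexniche.hexcluster import (
    ADJACENCY_MAX_DISTANCE,
    build_adjacency,
    cluster_readout,
    expand_and_merge,
    hex_ball_size,
    hex_neighborhood,
    hex_offsets,
    seed_clusters,
)
from scipy import sparse


# --- oracles ---------------------------------------------------------------

HEX_STEPS = [(1, 1), (1, -1), (-1, 1), (-1, -1), (0, 2), (0, -2)]


def bfs_ball(center, r, grid):
    """BFS ball of radius r on the 6-neighbour hex graph over an explicit
    parity grid."""
    frontier = {center}
    seen = {center}
    for _ in range(r):
        nxt = set()
        for (row, col) in frontier:
            for dj, di in HEX_STEPS:
                cand = (row + dj, col + di)
                if cand in grid and cand not in seen:
                    nxt.add(cand)
        seen |= nxt
        frontier = nxt
    return seen


def parity_grid(n_rows, n_cols):
    return {(r, c) for r in range(n_rows) for c in range(n_cols) if (r + c) % 2 == 0}


def brute_force_expand_merge(components, coords, r, universe):
    """Union-find-free oracle: expand every component, then repeatedly
    merge any two member sets that intersect."""
    sets = []
    for comp in components:
        seeds = {tuple(coords[i]) for i in comp}
        members = set()
        for s in seeds:
            members |= hex_neighborhood(s, r)
        members &= universe
        members |= seeds
        sets.append((seeds, members))
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(sets)), 2):
            if sets[a][1] & sets[b][1]:
                sa, ma = sets[a]
                sb, mb = sets[b]
                sets.append((sa | sb, ma | mb))
                for idx in sorted((a, b), reverse=True):
                    del sets[idx]
                changed = True
                break
    return {frozenset(m) for _, m in sets}


# --- hex_neighborhood ------------------------------------------------------


def test_radius_zero_is_center():
    assert hex_neighborhood((10, 10), 0) == {(10, 10)}


def test_radius_one_ring():
    assert hex_neighborhood((10, 10), 1) == {
        (10, 10),
        (10, 8),
        (10, 12),
        (9, 9),
        (9, 11),
        (11, 9),
        (11, 11),
    }


@pytest.mark.parametrize("r,size", [(2, 19), (3, 37)])
def test_centered_hexagonal_sizes(r, size):
    assert len(hex_neighborhood((20, 20), r)) == size == hex_ball_size(r)


@pytest.mark.parametrize("r", range(10))
def test_neighborhood_equals_bfs_ball(r):
    grid = parity_grid(50, 100)
    center = (25, 51)
    assert hex_neighborhood(center, r) == bfs_ball(center, r, grid)
    assert len(hex_neighborhood(center, r)) == 3 * r * r + 3 * r + 1


def test_offsets_have_even_parity():
    for r in range(6):
        assert all((j + i) % 2 == 0 for j, i in hex_offsets(r))


def test_negative_radius_fatal():
    with pytest.raises(ValueError):
        hex_neighborhood((0, 0), -1)


def test_bad_parity_center_fatal():
    with pytest.raises(ValueError):
        hex_neighborhood((0, 1), 1)


# --- build_adjacency -------------------------------------------------------


def test_diagonal_neighbors_linked():
    g = build_adjacency([(10, 10), (11, 11)])
    assert g.edges == [(0, 1)]  # distance sqrt(2)


def test_distance_two_boundary_inclusive():
    g = build_adjacency([(10, 10), (10, 12)])
    assert g.edges == [(0, 1)]


def test_distance_four_not_linked():
    g = build_adjacency([(10, 10), (10, 14)])
    assert g.edges == []


def test_strict_hex_drops_vertical_offset():
    # (2, 0) offset is within 2.0 but not a physical hex neighbour
    loose = build_adjacency([(10, 10), (12, 10)])
    strict = build_adjacency([(10, 10), (12, 10)], strict_hex=True)
    assert loose.edges == [(0, 1)]
    assert strict.edges == []


@given(
    st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30)).filter(
            lambda t: (t[0] + t[1]) % 2 == 0
        ),
        min_size=0,
        max_size=60,
        unique=True,
    )
)
@settings(max_examples=50, deadline=None)
def test_adjacency_equals_all_pairs(coords):
    g = build_adjacency(coords)
    arr = np.array(coords, dtype=float).reshape(-1, 2)
    expected = sorted(
        (a, b)
        for a in range(len(coords))
        for b in range(a + 1, len(coords))
        if np.hypot(*(arr[a] - arr[b])) <= ADJACENCY_MAX_DISTANCE
    )
    assert g.edges == expected


# --- seed_clusters ---------------------------------------------------------


def test_chain_is_one_component():
    g = build_adjacency([(10, 10), (10, 12), (10, 14)])
    comps = seed_clusters(g)
    assert [sorted(c) for c in comps] == [[0, 1, 2]]


def test_distant_spots_are_singletons():
    g = build_adjacency([(0, 0), (20, 20)])
    assert [sorted(c) for c in seed_clusters(g)] == [[0], [1]]


def test_empty_graph():
    assert seed_clusters(build_adjacency([])) == []


# --- expand_and_merge ------------------------------------------------------


def _clusters(coords, r, universe):
    g = build_adjacency(coords)
    comps = seed_clusters(g)
    return g, comps, expand_and_merge(comps, g, r, universe, "S")


def test_radius_zero_identity():
    universe = parity_grid(30, 30)
    coords = [(10, 10), (20, 20)]
    _, _, clusters = _clusters(coords, 0, universe)
    assert {c.seed_spots for c in clusters} == {
        frozenset({(10, 10)}),
        frozenset({(20, 20)}),
    }
    assert all(c.ring_spots == frozenset() for c in clusters)


def test_overlapping_rings_merge():
    universe = parity_grid(30, 30)
    # seeds 4 columns apart: radius-1 neighbourhoods share (10, 12)
    _, _, clusters = _clusters([(10, 10), (10, 14)], 1, universe)
    assert len(clusters) == 1
    assert clusters[0].seed_spots == frozenset({(10, 10), (10, 14)})


def test_merge_order_independent():
    universe = parity_grid(40, 40)
    coords = [(10, 10), (10, 14), (10, 18), (30, 30)]
    g = build_adjacency(coords)
    comps = seed_clusters(g)
    ref = {c.member_spots for c in expand_and_merge(comps, g, 2, universe, "S")}
    for perm in itertools.permutations(comps):
        out = expand_and_merge(list(perm), g, 2, universe, "S")
        assert {c.member_spots for c in out} == ref


def test_clusters_partition_members():
    universe = parity_grid(40, 40)
    rng = np.random.default_rng(3)
    coords = list(
        {(int(r), int(c)) for r, c in zip(rng.integers(0, 40, 40), rng.integers(0, 40, 40)) if (r + c) % 2 == 0}
    )
    _, _, clusters = _clusters(coords, 3, universe)
    seen = set()
    for c in clusters:
        assert not (c.member_spots & seen)
        seen |= c.member_spots


def test_membership_monotone_in_radius():
    universe = parity_grid(40, 40)
    coords = [(10, 10), (12, 14), (25, 25)]
    for r in range(9):
        _, _, small = _clusters(coords, r, universe)
        _, _, big = _clusters(coords, r + 1, universe)
        small_members = set().union(*(c.member_spots for c in small))
        big_members = set().union(*(c.member_spots for c in big))
        assert small_members <= big_members


def test_ring_spots_within_radius_of_seed():
    universe = parity_grid(40, 40)
    _, _, clusters = _clusters([(10, 10), (14, 14)], 2, universe)
    for c in clusters:
        for spot in c.ring_spots:
            assert any(
                spot in hex_neighborhood(s, c.radius) for s in c.seed_spots
            )


@given(
    st.lists(
        st.tuples(st.integers(0, 24), st.integers(0, 24)).filter(
            lambda t: (t[0] + t[1]) % 2 == 0
        ),
        min_size=1,
        max_size=40,
        unique=True,
    ),
    st.integers(0, 4),
)
@settings(max_examples=40, deadline=None)
def test_expand_merge_equals_brute_force(coords, r):
    universe = parity_grid(25, 25)
    g = build_adjacency(coords)
    comps = seed_clusters(g)
    got = {c.member_spots for c in expand_and_merge(comps, g, r, universe, "S")}
    expected = brute_force_expand_merge(comps, g.coords, r, universe)
    assert got == expected


# --- cluster_readout -------------------------------------------------------


def test_readout_sums():
    from hexniche.hexcluster import DensityCluster

    cluster = DensityCluster(
        cluster_id="S:10_10:r1",
        sample_id="S",
        radius=1,
        seed_spots=frozenset({(10, 10)}),
        ring_spots=frozenset({(9, 9), (9, 11)}),
    )
    coord_to_spot = {(10, 10): 0, (9, 9): 1, (9, 11): 2}
    counts = sparse.csr_matrix(
        np.array([[2, 10, 0], [0, 20, 5], [0, 10, 7]])
    )  # cols: cytokine, resp1, resp2
    out = cluster_readout(cluster, coord_to_spot, counts, 0, [1, 2])
    assert out.cytokine_count == 2
    assert out.responder_count == 10 + 0 + 20 + 5 + 10 + 7
    assert out.weight == 2


def test_readout_empty_signature():
    from hexniche.hexcluster import DensityCluster

    cluster = DensityCluster("c", "S", 0, frozenset({(0, 0)}), frozenset())
    counts = sparse.csr_matrix(np.array([[3, 1]]))
    out = cluster_readout(cluster, {(0, 0): 0}, counts, 0, [])
    assert out.responder_count == 0
    assert out.cytokine_count == 3
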