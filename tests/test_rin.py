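"""Residue interaction network: construction and centrality oracles.

Centralities are validated against independent brute-force oracles:
exhaustive BFS shortest-path enumeration for betweenness and closeness,
iterative pruning for the k-core number, and a direct matrix evaluation
of the constraint formula — on random graphs of up to 8 nodes and on the
full graph atlas up to 6 nodes.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from sevscan import fixtures as fx
from sevscan import structure
from sevscan.rin import build_rin, burt_constraint, compute_centralities


def _ca_residue(pos: int, xyz) -> structure.Residue:
    return structure.Residue(
        chain="A", seq_position=pos, insertion_code="", aa="A", resname="ALA",
        atoms=[structure.Atom("CA", "C", tuple(xyz), 10.0, 1.0)],
    )


# ---------------------------------------------------------------- oracles

def _bfs_paths(G, s):
    """(distance, path count) to every reachable node, by BFS layers."""
    dist, cnt = {s: 0}, {s: 1}
    layer = [s]
    while layer:
        nxt = []
        for u in layer:
            for v in G[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    cnt[v] = 0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    cnt[v] += cnt[u]
        layer = nxt
    return dist, cnt


def brute_betweenness(G):
    """Pair-count betweenness by explicit enumeration of shortest paths."""
    bc = {v: 0.0 for v in G}
    nodes = list(G)
    for s, t in itertools.combinations(nodes, 2):
        dist_s, cnt_s = _bfs_paths(G, s)
        if t not in dist_s:
            continue
        dist_t, cnt_t = _bfs_paths(G, t)
        total = cnt_s[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == dist_s[t]:
                bc[v] += cnt_s[v] * cnt_t[v] / total
    return bc


def brute_closeness(G):
    """Reachable-scaled closeness, computed from raw BFS distances."""
    n = len(G)
    out = {}
    for v in G:
        dist, _ = _bfs_paths(G, v)
        reach = len(dist) - 1
        total = sum(dist.values())
        if total == 0 or n < 2:
            out[v] = 0.0
        else:
            out[v] = (reach / total) * (reach / (n - 1))
    return out


def brute_kcore(G):
    """Core numbers by iterative minimum-degree pruning."""
    H = G.copy()
    core = {v: 0 for v in G}
    k = 0
    while H:
        while True:
            low = [v for v in H if H.degree(v) <= k]
            if not low:
                break
            for v in low:
                core[v] = k
                H.remove_node(v)
        k += 1
    return core


def brute_constraint(G, v):
    """Burt's constraint via dense proportional-strength matrices."""
    nodes = list(G)
    idx = {u: i for i, u in enumerate(nodes)}
    A = nx.to_numpy_array(G, nodelist=nodes)
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(deg[:, None] > 0, A / deg[:, None], 0.0)
    i = idx[v]
    if deg[i] == 0:
        return float("nan")
    total = 0.0
    for j in range(len(nodes)):
        if not A[i, j]:
            continue
        total += (P[i, j] + P[i] @ P[:, j]) ** 2
    return total


def random_graphs(n_graphs=200, max_nodes=8, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.1, 0.9))
        yield nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


# ------------------------------------------------------------ build_rin

class TestBuildRin:
    def test_edge_below_cutoff(self):
        res = [_ca_residue(1, (0, 0, 0)), _ca_residue(5, (4.9, 0, 0))]
        assert build_rin(res, contact_cutoff=5.0).number_of_edges() == 1

    def test_no_edge_above_cutoff(self):
        res = [_ca_residue(1, (0, 0, 0)), _ca_residue(5, (5.1, 0, 0))]
        assert build_rin(res, contact_cutoff=5.0).number_of_edges() == 0

    def test_single_residue_warns_and_has_no_edges(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            G = build_rin([_ca_residue(1, (0, 0, 0))])
        assert G.number_of_nodes() == 1 and G.number_of_edges() == 0

    def test_all_residues_are_nodes_even_isolated(self):
        res = [_ca_residue(1, (0, 0, 0)), _ca_residue(2, (3, 0, 0)),
               _ca_residue(9, (50, 0, 0))]
        G = build_rin(res)
        assert G.number_of_nodes() == 3
        assert G.degree("A:9") == 0

    def test_input_order_permutation_gives_identical_edges(self):
        spec = fx.SyntheticSpec(n_residues=25, geometry="random_coil", seed=9)
        res = structure.parse_structure(fx.make_toy_structure(spec))
        G1 = build_rin(res)
        rng = np.random.default_rng(3)
        shuffled = [res[i] for i in rng.permutation(len(res))]
        G2 = build_rin(shuffled)
        assert set(map(frozenset, G1.edges)) == set(map(frozenset, G2.edges))

    def test_min_sequence_separation_drops_chain_neighbours(self):
        spec = fx.SyntheticSpec(n_residues=10, geometry="extended", seed=2)
        res = structure.parse_structure(fx.make_toy_structure(spec))
        G = build_rin(res, min_sequence_separation=3)
        for u, v in G.edges:
            assert abs(G.nodes[u]["position"] - G.nodes[v]["position"]) >= 3

    def test_simple_graph_no_self_loops(self, strong_prep):
        G = strong_prep.network
        assert nx.number_of_selfloops(G) == 0


# -------------------------------------------------------- burt constraint

class TestBurtConstraint:
    def test_pendant_node_is_one(self):
        G = nx.path_graph(2)
        assert burt_constraint(G, 0) == pytest.approx(1.0)

    def test_triangle_nodes_are_1_125(self):
        G = nx.complete_graph(3)
        for v in G:
            assert burt_constraint(G, v) == pytest.approx(1.125)

    def test_star_center_is_quarter(self):
        G = nx.star_graph(4)
        assert burt_constraint(G, 0) == pytest.approx(0.25)

    def test_star_center_constraint_decreases_with_degree(self):
        values = [burt_constraint(nx.star_graph(k), 0) for k in range(1, 10)]
        assert values == pytest.approx([1.0 / k for k in range(1, 10)])
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_isolated_node_has_no_constraint(self):
        G = nx.Graph()
        G.add_node("x")
        assert np.isnan(burt_constraint(G, "x"))

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            burt_constraint(nx.path_graph(3), 99)

    def test_matches_brute_force_on_random_graphs(self):
        for G in random_graphs(200, 8, seed=10):
            for v in G:
                expected = brute_constraint(G, v)
                got = burt_constraint(G, v)
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_networkx_constraint(self):
        for G in random_graphs(30, 7, seed=4):
            ref = nx.constraint(G)
            for v in G:
                if G.degree(v) == 0:
                    continue
                assert burt_constraint(G, v) == pytest.approx(ref[v],
                                                              abs=1e-9)


# ------------------------------------------------------------ centralities

class TestCentralities:
    def test_path_graph_betweenness(self):
        G = nx.path_graph(3)
        cents, _ = compute_centralities(G)
        assert cents.loc[1, "betweenness"] == pytest.approx(1.0)
        assert cents.loc[0, "betweenness"] == pytest.approx(0.0)

    def test_triangle_degree_and_kcore(self):
        cents, _ = compute_centralities(nx.complete_graph(3))
        assert (cents["degree"] == 2).all()
        assert (cents["kcore"] == 2).all()

    def test_star_pagerank_center_dominates(self):
        cents, _ = compute_centralities(nx.star_graph(4))
        assert cents.loc[0, "pagerank"] > cents["pagerank"].iloc[1:].max()

    def test_pagerank_sums_to_one(self, strong_prep):
        assert strong_prep.centralities["pagerank"].sum() == pytest.approx(
            1.0, abs=1e-9)

    def test_kcore_bounded_by_degree(self, strong_prep):
        c = strong_prep.centralities
        assert (c["kcore"] <= c["degree"]).all()

    def test_betweenness_closeness_kcore_match_enumeration_on_atlas(self):
        # all non-isomorphic graphs on at most 6 nodes
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for G in graph_atlas_g():
            if G.number_of_nodes() > 6:
                break
            if G.number_of_nodes() == 0:
                continue
            cents, _ = compute_centralities(G)
            bb = brute_betweenness(G)
            cc = brute_closeness(G)
            kk = brute_kcore(G)
            for v in G:
                assert cents.loc[v, "betweenness"] == pytest.approx(
                    bb[v], abs=1e-9)
                assert cents.loc[v, "closeness"] == pytest.approx(
                    cc[v], abs=1e-9)
                assert cents.loc[v, "kcore"] == kk[v]
            checked += 1
        assert checked > 200  # the atlas holds 208 graphs on <= 6 nodes
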