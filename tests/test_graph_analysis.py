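"""Shortest paths and motif matching against brute-force oracles."""

from itertools import permutations, product

import networkx as nx
import pytest

from sbgngraph import (
    MotifPattern, build_graph, find_motifs, generate_suite,
    generate_toy_metabolism, shortest_path, Language,
)
from sbgngraph.errors import (
    AmbiguousLabelError, StructuralError, UnresolvedReferenceError,
)
from sbgngraph.simplifier import simplify


# ---------------------------------------------------------------------------
# independent oracles

def bfs_hops(g, src, tgt, directed):
    """Brute-force breadth-first hop count, None if unreachable."""
    h = g if directed else g.to_undirected(as_view=True)
    frontier, dist, seen = [src], 0, {src}
    while frontier:
        if tgt in frontier:
            return dist
        nxt = []
        for n in frontier:
            for nbr in h.neighbors(n):
                if nbr not in seen:
                    seen.add(nbr)
                    nxt.append(nbr)
        frontier, dist = nxt, dist + 1
    return None


def enumerate_motifs(g, pattern):
    """Exhaustive enumeration over all injective node mappings."""
    from sbgngraph.graph_analysis import _edge_classes, _node_ok, \
        _pattern_automorphisms
    names = sorted(pattern.nodes)
    hits = set()
    for combo in permutations(sorted(g.nodes), len(names)):
        mapping = dict(zip(names, combo))
        if not all(_node_ok(pattern.nodes[n], g.nodes[mapping[n]])
                   for n in names):
            continue
        ok = True
        for u, v, c in pattern.edges:
            classes = _edge_classes(g, mapping[u], mapping[v],
                                    pattern.directed)
            if not classes or (c is not None and c not in classes):
                ok = False
                break
        if not ok:
            continue
        autos = _pattern_automorphisms(pattern)
        canon = min(tuple(mapping[a[n]] for n in names) for a in autos)
        hits.add(canon)
    return hits


# ---------------------------------------------------------------------------

class TestShortestPath:
    def test_toy_chain_directed_traversal(self, toy_graph):
        """pyruvate -> succinate crosses 4 metabolites + 3 processes:
        7 nodes, 6 hops (frozen from the brute-force oracle on the
        simplified chain)."""
        path = shortest_path(toy_graph, "pyruvate", "succinate",
                             directed=True)
        assert len(path) == 7
        assert len(path) - 1 == 6
        simplified, _ = simplify(toy_graph)
        src = next(n for n, d in simplified.nodes(data=True)
                   if d.get("label") == "pyruvate")
        tgt = next(n for n, d in simplified.nodes(data=True)
                   if d.get("label") == "succinate")
        assert bfs_hops(simplified, src, tgt, directed=True) == 6

    def test_merged_cofactors_shorten_undirected_path(self, toy_graph):
        """undirected, the merged ADP pool short-circuits the chain; the
        oracle agrees."""
        path = shortest_path(toy_graph, "pyruvate", "succinate",
                             directed=False)
        simplified, _ = simplify(toy_graph)
        src = next(n for n, d in simplified.nodes(data=True)
                   if d.get("label") == "pyruvate")
        tgt = next(n for n, d in simplified.nodes(data=True)
                   if d.get("label") == "succinate")
        assert len(path) - 1 == bfs_hops(simplified, src, tgt, directed=False)

    def test_source_equals_target(self, toy_graph):
        assert shortest_path(toy_graph, "pyruvate", "pyruvate") == ["m0"]

    def test_disconnected_returns_none(self):
        g = nx.MultiDiGraph()
        g.add_node("a", label="a")
        g.add_node("b", label="b")
        assert shortest_path(g, "a", "b") is None

    def test_unknown_endpoint_raises(self, toy_graph):
        with pytest.raises(UnresolvedReferenceError):
            shortest_path(toy_graph, "pyruvate", "citrate")

    def test_ambiguous_label_lists_candidates(self):
        g = nx.MultiDiGraph()
        g.add_node("x1", label="X")
        g.add_node("x2", label="X")
        g.add_node("y", label="Y")
        g.add_edge("x1", "y")
        g.add_edge("x2", "y")
        with pytest.raises(AmbiguousLabelError) as err:
            shortest_path(g, "X", "Y", raw=True)
        assert err.value.candidates == ["x1", "x2"]

    def test_lexicographic_tie_break(self):
        g = nx.MultiDiGraph()
        for mid in ("b", "c"):
            g.add_edge("a", mid)
            g.add_edge(mid, "d")
        assert shortest_path(g, "a", "d", raw=True) == ["a", "b", "d"]

    def test_oracle_equivalence_over_fixture_graphs(self, all_suite_cases):
        """hop counts agree with brute-force BFS on every small graph."""
        for spec, doc in all_suite_cases:
            g = build_graph(doc.map, decompose=True)
            if g.number_of_nodes() > 12:
                continue
            nodes = sorted(g.nodes)
            for src, tgt in product(nodes[:4], nodes[:4]):
                for directed in (False, True):
                    expected = bfs_hops(g, src, tgt, directed)
                    got = shortest_path(g, src, tgt, directed=directed,
                                        raw=True)
                    if expected is None:
                        assert got is None, (spec.name, src, tgt)
                    else:
                        assert len(got) - 1 == expected, (spec.name, src, tgt)

    def test_simplified_never_longer_than_raw(self, toy_graph):
        for directed in (False, True):
            simple = shortest_path(toy_graph, "pyruvate", "succinate",
                                   directed=directed)
            raw = shortest_path(toy_graph, "m0", "m3", directed=directed,
                                raw=True)
            assert len(simple) <= len(raw)


class TestFindMotifs:
    def test_consumption_motif_on_toy_chain(self, toy_graph):
        """EPN -> process consumption pattern matches chain and ATP edges."""
        pattern = MotifPattern(nodes={"e": "epn", "p": "process"},
                               edges=[("e", "p", "consumption")])
        matches = find_motifs(toy_graph, pattern)
        expected = {(u, v) for u, v, d in toy_graph.edges(data=True)
                    if d.get("cls") == "consumption"}
        assert {(m["e"], m["p"]) for m in matches} == expected
        assert len(matches) == 6  # 3 chain + 3 ATP consumptions

    def test_pattern_larger_than_graph(self):
        g = nx.MultiDiGraph()
        g.add_edge("a", "b")
        pattern = MotifPattern(nodes={"x": None, "y": None, "z": None},
                               edges=[("x", "y"), ("y", "z")])
        assert find_motifs(g, pattern) == []

    def test_single_unconstrained_node_matches_every_node(self, toy_graph):
        matches = find_motifs(toy_graph, MotifPattern(nodes={"n": None}))
        assert len(matches) == toy_graph.number_of_nodes()

    def test_automorphic_duplicates_reported_once(self):
        g = nx.MultiDiGraph()
        g.add_edge("a", "b")
        g.add_edge("b", "a")
        pattern = MotifPattern(nodes={"x": None, "y": None},
                               edges=[("x", "y")], directed=False)
        assert len(find_motifs(g, pattern)) == 1

    def test_oversized_pattern_rejected(self):
        nodes = {f"n{i}": None for i in range(7)}
        edges = [(f"n{i}", f"n{i + 1}") for i in range(6)]
        with pytest.raises(StructuralError, match="bound"):
            find_motifs(nx.MultiDiGraph(), MotifPattern(nodes, edges))

    def test_disconnected_pattern_rejected(self):
        pattern = MotifPattern(nodes={"a": None, "b": None}, edges=())
        with pytest.raises(StructuralError, match="connected"):
            find_motifs(nx.MultiDiGraph(), pattern)

    @pytest.mark.parametrize("directed", [True, False])
    def test_oracle_equivalence_exhaustive(self, directed, all_suite_cases):
        """matches equal exhaustive enumeration on every fixture graph
        with <= 12 nodes."""
        patterns = [
            MotifPattern(nodes={"a": None, "b": None}, edges=[("a", "b")],
                         directed=directed),
            MotifPattern(nodes={"a": "epn", "b": None},
                         edges=[("a", "b", "necessary stimulation")],
                         directed=directed),
            MotifPattern(nodes={"a": None, "b": None, "c": None},
                         edges=[("a", "b"), ("b", "c")], directed=directed),
        ]
        for spec, doc in all_suite_cases[::5]:
            g = build_graph(doc.map, decompose=False)
            if g.number_of_nodes() > 12:
                continue
            for pattern in patterns:
                names = sorted(pattern.nodes)
                got = {tuple(m[n] for n in names)
                       for m in find_motifs(g, pattern)}
                # canonicalise like the oracle for comparison
                expected = enumerate_motifs(g, pattern)
                from sbgngraph.graph_analysis import _pattern_automorphisms
                autos = _pattern_automorphisms(pattern)
                got_canon = {min(tuple(dict(zip(names, t))[a[n]]
                                       for n in names) for a in autos)
                             for t in got}
                assert got_canon == expected, (spec.name, pattern)

    def test_deterministic_order(self, toy_graph):
        pattern = MotifPattern(nodes={"e": "epn", "p": "process"},
                               edges=[("e", "p", "consumption")])
        assert find_motifs(toy_graph, pattern) == \
            find_motifs(toy_graph, pattern)
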