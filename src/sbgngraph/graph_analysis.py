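"""Network analyses on SBGN property graphs.

Two demonstration analyses made first-class: minimum-hop shortest paths
between named entities (e.g. pyruvate to succinate in a metabolic map)
and labeled-motif matching by subgraph monomorphism.

Both run on the *simplified* graph by default — auxiliary nodes
introduced by composite-edge decomposition carry no biological meaning
but would still be counted by topology algorithms, and simplification
is the designed remedy.  Pass ``raw=True`` to analyse the graph as
built.

Determinism contracts: among equal-length shortest paths the
lexicographically smallest node-id sequence is returned; motif matches
are deduplicated under pattern automorphisms and reported in sorted
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional

import networkx as nx

from .errors import AmbiguousLabelError, StructuralError, UnresolvedReferenceError
from .simplifier import simplify

__all__ = ["MotifPattern", "shortest_path", "find_motifs", "resolve_node"]

#: PD entity-pool node classes, usable as the "epn" meta-class in patterns
EPN_CLASSES = frozenset({
    "unspecified entity", "simple chemical", "macromolecule",
    "nucleic acid feature", "complex", "simple chemical multimer",
    "macromolecule multimer", "nucleic acid feature multimer",
    "complex multimer", "source and sink", "perturbing agent",
})

_MAX_PATTERN_NODES = 6


def resolve_node(g: nx.MultiDiGraph, ref: str) -> str:
    """Resolve a node id or unique label to a node id."""
    if ref in g:
        return ref
    candidates = sorted(n for n, d in g.nodes(data=True)
                        if d.get("label") == ref)
    if not candidates:
        raise UnresolvedReferenceError(
            f"no node with id or label {ref!r}", ids=[ref])
    if len(candidates) > 1:
        raise AmbiguousLabelError(
            f"label {ref!r} matches {len(candidates)} nodes: "
            + ", ".join(candidates), candidates=candidates)
    return candidates[0]


def shortest_path(g: nx.MultiDiGraph, source: str, target: str,
                  directed: bool = False, raw: bool = False
                  ) -> Optional[list[str]]:
    """Minimum-hop path between two nodes named by id or unique label.

    Returns the ordered node list, or ``None`` when the endpoints are
    disconnected.  Among equal-length paths the lexicographically
    smallest id sequence wins.  Unless ``raw`` is set the search runs on
    the simplified graph (auxiliary/container nodes removed, clones
    merged); the endpoints are resolved after simplification.
    """
    h = g if raw else simplify(g)[0]
    src = resolve_node(h, source)
    tgt = resolve_node(h, target)
    search: nx.Graph = h if directed else h.to_undirected(as_view=True)

    # distance-to-target per node, then greedy lexicographic reconstruction
    if directed:
        dist = nx.single_source_shortest_path_length(search.reverse(copy=False),
                                                     tgt)
    else:
        dist = nx.single_source_shortest_path_length(search, tgt)
    if src not in dist:
        return None
    path = [src]
    node = src
    while node != tgt:
        steps = sorted(nbr for nbr in search.neighbors(node)
                       if dist.get(nbr) == dist[node] - 1)
        node = steps[0]
        path.append(node)
    return path


# ---------------------------------------------------------------------------
# Motif matching

@dataclass(frozen=True)
class MotifPattern:
    """A small labeled pattern graph for motif search.

    ``nodes`` maps pattern-node names to an optional class constraint:
    ``None`` (any node), a class token, the meta-token ``"epn"`` (any
    entity-pool class), or a tuple of class tokens.  ``edges`` is a list
    of (source, target, arc-class-or-None).  Patterns must be connected
    and have at most 6 nodes (brute-force tractability bound).
    """

    nodes: dict = field(default_factory=dict)
    edges: tuple = ()
    directed: bool = True
    induced: bool = False

    def __post_init__(self):
        object.__setattr__(self, "edges", tuple(
            (e[0], e[1], e[2] if len(e) == 3 else None) for e in self.edges))

    def validate(self) -> None:
        if not self.nodes:
            raise StructuralError("pattern has no nodes")
        if len(self.nodes) > _MAX_PATTERN_NODES:
            raise StructuralError(
                f"pattern has {len(self.nodes)} nodes; the bound is "
                f"{_MAX_PATTERN_NODES}")
        for u, v, _ in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise StructuralError(f"pattern edge ({u}, {v}) names an "
                                      "undeclared node")
        if len(self.nodes) > 1:
            und = nx.Graph()
            und.add_nodes_from(self.nodes)
            und.add_edges_from((u, v) for u, v, _ in self.edges)
            if not nx.is_connected(und):
                raise StructuralError("pattern must be connected")


def _node_ok(constraint, data: dict) -> bool:
    if constraint is None:
        return True
    cls = data.get("cls")
    if isinstance(constraint, (tuple, list, set, frozenset)):
        return cls in constraint
    if constraint == "epn":
        return cls in EPN_CLASSES
    return cls == constraint


def _edge_classes(g: nx.MultiDiGraph, u: str, v: str,
                  directed: bool) -> set:
    out = set()
    if g.has_edge(u, v):
        out |= {d.get("cls") for d in g[u][v].values()}
    if not directed and g.has_edge(v, u):
        out |= {d.get("cls") for d in g[v][u].values()}
    return out


def _pattern_automorphisms(pattern: MotifPattern) -> list[dict]:
    """All node bijections of the pattern onto itself preserving
    constraints and edges (brute force; patterns are tiny)."""
    names = sorted(pattern.nodes)
    edge_set = {(u, v, c) for u, v, c in pattern.edges}
    if not pattern.directed:
        edge_set |= {(v, u, c) for u, v, c in pattern.edges}
    autos = []
    for perm in permutations(names):
        m = dict(zip(names, perm))
        if any(pattern.nodes[a] != pattern.nodes[m[a]] for a in names):
            continue
        mapped = {(m[u], m[v], c) for u, v, c in edge_set}
        if mapped == edge_set:
            autos.append(m)
    return autos


def find_motifs(g: nx.MultiDiGraph, pattern: MotifPattern,
                raw: bool = True) -> list[dict]:
    """All injective embeddings of ``pattern`` into ``g``.

    Backtracking subgraph monomorphism (non-induced by default — extra
    host edges between matched nodes are allowed; ``pattern.induced``
    switches to induced semantics).  Embeddings equivalent under a
    pattern automorphism are reported once; output order is
    deterministic (sorted by mapped host ids).
    """
    pattern.validate()
    h = g if raw else simplify(g)[0]
    names = sorted(pattern.nodes)
    host_nodes = sorted(h.nodes)

    def edge_ok(pu: str, pv: str, need_cls, hu: str, hv: str) -> bool:
        classes = _edge_classes(h, hu, hv, pattern.directed)
        if not classes:
            return False
        return need_cls is None or need_cls in classes

    results: list[tuple] = []

    def backtrack(i: int, mapping: dict) -> None:
        if i == len(names):
            if pattern.induced:
                for pu, pv in permutations(names, 2):
                    if not any(u == pu and v == pv for u, v, _ in pattern.edges) \
                            and (pattern.directed or not any(
                                u == pv and v == pu
                                for u, v, _ in pattern.edges)):
                        if pattern.directed:
                            if h.has_edge(mapping[pu], mapping[pv]):
                                return
                        elif _edge_classes(h, mapping[pu], mapping[pv], False):
                            return
            results.append(tuple(mapping[n] for n in names))
            return
        name = names[i]
        used = set(mapping.values())
        for cand in host_nodes:
            if cand in used:
                continue
            if not _node_ok(pattern.nodes[name], h.nodes[cand]):
                continue
            ok = True
            for u, v, c in pattern.edges:
                if u == name and v in mapping:
                    ok = edge_ok(u, v, c, cand, mapping[v])
                elif v == name and u in mapping:
                    ok = edge_ok(u, v, c, mapping[u], cand)
                else:
                    continue
                if not ok:
                    break
            if ok:
                mapping[name] = cand
                backtrack(i + 1, mapping)
                del mapping[name]

    backtrack(0, {})

    autos = _pattern_automorphisms(pattern)
    seen: set[tuple] = set()
    unique: list[dict] = []
    for tup in sorted(results):
        mapping = dict(zip(names, tup))
        canon = min(tuple(mapping[a[n]] for n in names) for a in autos)
        if canon in seen:
            continue
        seen.add(canon)
        unique.append(mapping)
    return unique
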