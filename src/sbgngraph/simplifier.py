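"""Diagram simplification for topology analysis.

Layout and path/motif algorithms assume a plain entity/process graph;
SBGN diagrams add containers (compartments, tags, submaps), clone-marked
duplicates of pooled species (ATP, ADP, ...) and — after composite-edge
decomposition — auxiliary nodes with no biological meaning.  The
simplifier produces a cleaned *copy* of the graph (the input is never
modified):

* decomposed arc pairs are collapsed back to one edge carrying the
  original arc class — only the edge shape changed, the type attribute
  is preserved;
* compartment/tag/submap/terminal nodes are dropped with their incident
  containment and equivalence edges (the ``compartment`` attribute on
  member nodes is retained as text, so no information is lost);
* clone-marked nodes sharing (class, label) are merged into one
  surviving node — merged, not deleted, because deleting them would
  disconnect every reaction the cloned species participates in.

Unlabeled clone glyphs are never merged: (class, label) is the only
identity SBGN-ML offers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import StructuralError

__all__ = ["SimplificationReport", "simplify", "merge_clones",
           "collapse_composites"]

#: node classes removed outright, keyed by the report category they land in
_REMOVAL_REASON = {"compartment": "compartment", "tag": "tag",
                   "submap": "submap", "terminal": "submap"}


@dataclass
class SimplificationReport:
    """What one simplification pass removed, merged and collapsed."""

    removed: dict[str, str] = field(default_factory=dict)  # node id -> reason
    clone_groups: list[tuple[str, list[str]]] = field(default_factory=list)
    collapsed_arcs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed": dict(self.removed),
            "clone_groups": [{"survivor": s, "absorbed": a}
                             for s, a in self.clone_groups],
            "collapsed_arcs": list(self.collapsed_arcs),
        }


def collapse_composites(g: nx.MultiDiGraph,
                        report: SimplificationReport | None = None
                        ) -> nx.MultiDiGraph:
    """Replace every auxiliary node and its two incident sub-edges by a
    single edge of the original arc class.  Inverse of decomposition."""
    h = g.copy()
    aux_nodes = [n for n, d in h.nodes(data=True) if d.get("is_auxiliary")]
    for aux in aux_nodes:
        in_edges = list(h.in_edges(aux, keys=True, data=True))
        out_edges = list(h.out_edges(aux, keys=True, data=True))
        if len(in_edges) != 1 or len(out_edges) != 1:
            raise StructuralError(
                f"auxiliary node {aux!r} has degree "
                f"{len(in_edges) + len(out_edges)}, expected 2")
        (src, _, _, first), (_, tgt, _, second) = in_edges[0], out_edges[0]
        arc_id = first.get("original_arc")
        if arc_id is None or second.get("original_arc") != arc_id:
            raise StructuralError(
                f"auxiliary node {aux!r} lost its original_arc provenance")
        attrs = {"cls": first.get("original_class"),
                 "original_arc": arc_id, "segment": "none"}
        if "cardinality" in first:
            attrs["cardinality"] = first["cardinality"]
        h.remove_node(aux)
        h.add_edge(src, tgt, key=arc_id, **attrs)
        if report is not None:
            report.collapsed_arcs.append(arc_id)
    return h


def merge_clones(g: nx.MultiDiGraph,
                 report: SimplificationReport | None = None
                 ) -> nx.MultiDiGraph:
    """Merge clone-flagged nodes sharing (cls, label) into one node.

    The lexicographically smallest id survives; incident edges are
    rewired to it and parallel edges with identical (source, target,
    class) are deduplicated.
    """
    h = g.copy()
    groups: dict[tuple[str, str], list[str]] = {}
    for n, d in h.nodes(data=True):
        if d.get("clone") and d.get("label"):
            groups.setdefault((d.get("cls"), d["label"]), []).append(n)

    for key in sorted(groups):
        members = sorted(groups[key])
        if len(members) < 2:
            continue
        survivor, absorbed = members[0], members[1:]
        for node in absorbed:
            for u, _, k, d in list(h.in_edges(node, keys=True, data=True)):
                h.remove_edge(u, node, key=k)
                src = survivor if u == node else u
                h.add_edge(src, survivor, key=k, **d)
            for _, v, k, d in list(h.out_edges(node, keys=True, data=True)):
                if h.has_edge(node, v, key=k):
                    h.remove_edge(node, v, key=k)
                    tgt = survivor if v == node else v
                    h.add_edge(survivor, tgt, key=k, **d)
            h.remove_node(node)
        if report is not None:
            report.clone_groups.append((survivor, absorbed))

    # deduplicate parallel edges with identical (source, target, cls) that
    # arose from the rewiring; edges not touching a survivor are left alone
    survivors = {s for s, _ in (report.clone_groups if report else [])} or \
        {sorted(groups[k])[0] for k in groups if len(groups[k]) > 1}
    seen: set[tuple[str, str, str]] = set()
    to_drop = []
    for u, v, k, d in h.edges(keys=True, data=True):
        if u not in survivors and v not in survivors:
            continue
        sig = (u, v, d.get("cls"))
        if sig in seen:
            to_drop.append((u, v, k))
        else:
            seen.add(sig)
    for u, v, k in to_drop:
        h.remove_edge(u, v, key=k)
    return h


def simplify(g: nx.MultiDiGraph) -> tuple[nx.MultiDiGraph, SimplificationReport]:
    """Full simplification pass; returns a new graph, input untouched.

    Order: collapse decomposed arcs, drop container/annotation nodes,
    merge clones.  Idempotent: simplifying a simplified graph is a
    no-op.
    """
    report = SimplificationReport()
    h = collapse_composites(g, report)
    for node in [n for n, d in h.nodes(data=True)
                 if d.get("cls") in _REMOVAL_REASON]:
        report.removed[node] = _REMOVAL_REASON[h.nodes[node]["cls"]]
        h.remove_node(node)
    h = merge_clones(h, report)
    return h, report
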