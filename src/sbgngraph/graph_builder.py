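"""Convert an SBGN map into an attribute-rich property graph.

The analysis representation is a :class:`networkx.MultiDiGraph` whose
nodes and edges carry attribute maps mirroring everything stored in the
SBGN-ML file (class, label, geometry, compartment, provenance ids).

Three arc classes combine two terminal decorations and have no single
simple-edge equivalent: *necessary stimulation*, *absolute stimulation*
and *absolute inhibition*.  These are decomposed into two sub-edges
joined by a small invisible auxiliary node placed at the arc midpoint —
necessary stimulation splits into an inhibition edge followed by a
stimulation edge; the two absolute classes double their base decoration
(stimulation+stimulation, inhibition+inhibition).  Both sub-edges keep
the original arc id and class as attributes so the simplifier can invert
the decomposition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import pandas as pd

from .core_model import (
    AUX_UNIT_CLASSES, Arc, Glyph, SbgnMap, glyph_center,
)
from .errors import StructuralError, UnresolvedReferenceError

__all__ = ["ShapeRecipe", "DEFAULT_RECIPES", "build_graph", "decompose_arc",
           "attribute_table", "DECOMPOSED_CLASSES"]


@dataclass(frozen=True)
class ShapeRecipe:
    """How to realise one arc class: directly, or as two sub-edges.

    ``direct`` recipes carry a style token; ``decomposed`` recipes carry
    the classes of the first and second sub-edge segment.
    """

    arc_cls: str
    first: Optional[str] = None
    second: Optional[str] = None

    @property
    def decomposed(self) -> bool:
        return self.first is not None


DEFAULT_RECIPES: dict[str, ShapeRecipe] = {
    "necessary stimulation": ShapeRecipe("necessary stimulation",
                                         "inhibition", "stimulation"),
    "absolute stimulation": ShapeRecipe("absolute stimulation",
                                        "stimulation", "stimulation"),
    "absolute inhibition": ShapeRecipe("absolute inhibition",
                                       "inhibition", "inhibition"),
}

DECOMPOSED_CLASSES = frozenset(DEFAULT_RECIPES)


def _arc_midpoint(arc: Arc) -> tuple[float, float]:
    if arc.bends:
        return arc.bends[(len(arc.bends) - 1) // 2]
    return ((arc.start[0] + arc.end[0]) / 2.0,
            (arc.start[1] + arc.end[1]) / 2.0)


def decompose_arc(arc: Arc, recipe: ShapeRecipe):
    """Split one composite arc into (auxiliary node, first edge, second edge).

    The auxiliary node sits at the arc's geometric midpoint (middle bend
    point when bends exist) with near-zero extent; both sub-edges carry
    the original arc id and class for reversibility.
    """
    if not recipe.decomposed:
        raise StructuralError(
            f"arc {arc.id!r} of class {arc.cls!r} has a direct recipe; "
            "nothing to decompose")
    mx, my = _arc_midpoint(arc)
    aux_id = f"{arc.id}.aux"
    aux_attrs = {
        "cls": "auxiliary", "label": None, "x": mx, "y": my,
        "width": 0.1, "height": 0.1, "compartment": None,
        "is_auxiliary": True, "source_glyph": None,
    }
    common = {"original_arc": arc.id, "original_class": arc.cls}
    first = (f"{arc.id}.1", {"cls": recipe.first, "segment": "first", **common})
    second = (f"{arc.id}.2", {"cls": recipe.second, "segment": "second", **common})
    return (aux_id, aux_attrs), first, second


def _node_attrs(g: Glyph) -> dict:
    cx, cy = glyph_center(g)
    attrs = {
        "cls": g.cls, "label": g.label, "x": cx, "y": cy,
        "width": g.bbox.w, "height": g.bbox.h,
        "compartment": g.compartment_ref,
        "is_auxiliary": False, "source_glyph": g.id,
    }
    if g.clone:
        attrs["clone"] = True
    if g.orientation is not None:
        attrs["orientation"] = g.orientation
    states = [c.label for c in g.children if c.cls == "state variable"]
    units = [c.label for c in g.children if c.cls == "unit of information"]
    if states:
        attrs["state_variables"] = ";".join(s or "" for s in states)
    if units:
        attrs["units_of_information"] = ";".join(u or "" for u in units)
    return attrs


def build_graph(map: SbgnMap, decompose: bool = True,
                recipes: Optional[dict[str, ShapeRecipe]] = None
                ) -> nx.MultiDiGraph:
    """Build the property graph for a map.

    One node per glyph that is not an auxiliary unit — compartments,
    tags, submaps and logic operators included; state variables and
    units of information become attributes of their parent node instead.
    Sub-glyphs that are themselves entities (complex members, submap
    terminals) become nodes linked to the parent by a containment edge
    of class ``"part of"``.  Port references are resolved to the owning
    glyph.  With ``decompose=True`` every arc of a composite class is
    replaced per :func:`decompose_arc`; otherwise arcs pass through
    unchanged.
    """
    recipes = DEFAULT_RECIPES if recipes is None else recipes
    g = nx.MultiDiGraph(language=map.language.value)

    def add_glyph(glyph: Glyph, parent: Optional[str]) -> None:
        if glyph.cls in AUX_UNIT_CLASSES:
            return
        g.add_node(glyph.id, **_node_attrs(glyph))
        if parent is not None:
            g.add_edge(parent, glyph.id, key=f"{parent}.{glyph.id}.part",
                       cls="part of", original_arc=None, segment="none",
                       containment=True)
        for child in glyph.children:
            add_glyph(child, glyph.id)

    for glyph in map.glyphs:
        add_glyph(glyph, None)

    port_owner = {pid: owner.id for pid, owner in map.port_owner_index().items()}

    def resolve(ref: str, arc_id: str) -> str:
        if ref in g:
            return ref
        if ref in port_owner:
            return port_owner[ref]
        raise UnresolvedReferenceError(
            f"arc {arc_id!r}: endpoint {ref!r} resolves to no glyph or port",
            ids=[ref])

    for arc in map.arcs:
        src = resolve(arc.source, arc.id)
        tgt = resolve(arc.target, arc.id)
        attrs = {"cls": arc.cls, "original_arc": arc.id, "segment": "none"}
        if arc.cardinality is not None:
            attrs["cardinality"] = arc.cardinality
        if decompose and arc.cls in recipes and recipes[arc.cls].decomposed:
            (aux_id, aux_attrs), (k1, a1), (k2, a2) = \
                decompose_arc(arc, recipes[arc.cls])
            g.add_node(aux_id, **aux_attrs)
            g.add_edge(src, aux_id, key=k1, **a1)
            g.add_edge(aux_id, tgt, key=k2, **a2)
        else:
            g.add_edge(src, tgt, key=arc.id, **attrs)
    return g


def attribute_table(g: nx.MultiDiGraph, kind: str) -> pd.DataFrame:
    """Tabular node or edge attribute records (Cytoscape-importable).

    One row per node/edge in insertion order; columns are the union of
    attribute keys in first-appearance order; missing values are empty
    strings.
    """
    rows = []
    columns: list[str] = []
    if kind == "node":
        columns.append("id")
        for node, data in g.nodes(data=True):
            row = {"id": node, **data}
            rows.append(row)
            for key in data:
                if key not in columns:
                    columns.append(key)
    elif kind == "edge":
        columns += ["id", "source", "target"]
        for u, v, key, data in g.edges(keys=True, data=True):
            row = {"id": key, "source": u, "target": v, **data}
            rows.append(row)
            for k in data:
                if k not in columns:
                    columns.append(k)
    else:
        raise ValueError(f"kind must be 'node' or 'edge', got {kind!r}")
    table = pd.DataFrame(rows, columns=columns)
    return table.fillna("") if not table.empty else table
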