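"""SBGN-ML reading and writing.

SBGN-ML is the XML serialisation of SBGN maps implemented by libSBGN.
The target dialect is the milestone-0.2 namespace
(``http://sbgn.org/libsbgn/0.2``); the reader accepts any ``sbgn.org``
namespace and records which one it saw, so files written by later tools
still load.  Every stored attribute — glyph classes, labels, bounding
boxes, ports, clone markers, arc geometry, cardinalities — is captured;
elements the reader does not recognise are kept verbatim in a ledger and
re-emitted on write, never dropped silently.

Coordinates are stored exactly as in the file (top-left corner + extent);
centers are a computed view (:func:`sbgngraph.core_model.glyph_center`).
Numbers are written in their shortest round-trip decimal form so that
read -> write -> read is loss-free.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field
from typing import BinaryIO, Union

from lxml import etree

from .core_model import (
    Arc, BBox, Glyph, Language, Port, SbgnMap, glyph_center, validate_map,
)
from .errors import SbgnFormatError, UnresolvedReferenceError

__all__ = ["SbgnDocument", "read_map", "write_map", "apply_layout",
           "DEFAULT_NAMESPACE"]

DEFAULT_NAMESPACE = "http://sbgn.org/libsbgn/0.2"

_KNOWN_GLYPH_CHILDREN = {"label", "bbox", "port", "glyph", "clone", "state"}
_KNOWN_ARC_CHILDREN = {"start", "end", "next", "glyph"}

Source = Union[str, os.PathLike, bytes, BinaryIO]


@dataclass
class SbgnDocument:
    """A parsed SBGN-ML document: the map plus serialisation context."""

    map: SbgnMap
    namespace: str = DEFAULT_NAMESPACE
    #: (parent element id or "", raw XML fragment) for unrecognised elements
    unrecognized: list[tuple[str, str]] = field(default_factory=list)


def _localname(el) -> str:
    return etree.QName(el).localname


def _parse_float(value: str, context: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SbgnFormatError(f"non-numeric coordinate {value!r} in {context}")


def _parse_point(el, context: str) -> tuple[float, float]:
    return (_parse_float(el.get("x"), context), _parse_float(el.get("y"), context))


def _parse_glyph(el, ledger: list[tuple[str, str]]) -> Glyph:
    gid = el.get("id")
    cls = el.get("class")
    if gid is None or cls is None:
        raise SbgnFormatError(
            f"glyph missing id or class at line {el.sourceline}")
    label = None
    bbox = BBox(0.0, 0.0, 0.0, 0.0)
    ports: list[Port] = []
    children: list[Glyph] = []
    clone = False
    for child in el:
        if not isinstance(child.tag, str):
            continue  # comments / PIs
        name = _localname(child)
        if name == "label":
            label = child.get("text")
        elif name == "bbox":
            ctx = f"bbox of glyph {gid}"
            bbox = BBox(_parse_float(child.get("x"), ctx),
                        _parse_float(child.get("y"), ctx),
                        _parse_float(child.get("w"), ctx),
                        _parse_float(child.get("h"), ctx))
        elif name == "port":
            ctx = f"port of glyph {gid}"
            ports.append(Port(child.get("id"), *_parse_point(child, ctx)))
        elif name == "glyph":
            children.append(_parse_glyph(child, ledger))
        elif name == "clone":
            clone = True
        elif name == "state":
            # milestone-0.2 state variables carry value/variable attributes;
            # fold them into the label ("value@variable" convention)
            value = child.get("value") or ""
            variable = child.get("variable") or ""
            label = f"{value}@{variable}" if variable else value
        else:
            ledger.append((gid, etree.tostring(child, encoding="unicode")))
    g = Glyph(id=gid, cls=cls, bbox=bbox, label=label,
              compartment_ref=el.get("compartmentRef"),
              ports=ports, children=children, clone=clone,
              orientation=el.get("orientation"))
    return g


def _parse_arc(el, ledger: list[tuple[str, str]]) -> Arc:
    aid = el.get("id")
    cls = el.get("class")
    src = el.get("source")
    tgt = el.get("target")
    if None in (aid, cls, src, tgt):
        raise SbgnFormatError(f"arc missing id/class/source/target at line "
                              f"{el.sourceline}")
    start = end = (0.0, 0.0)
    bends: list[tuple[float, float]] = []
    cardinality = None
    for child in el:
        if not isinstance(child.tag, str):
            continue
        name = _localname(child)
        ctx = f"arc {aid}"
        if name == "start":
            start = _parse_point(child, ctx)
        elif name == "end":
            end = _parse_point(child, ctx)
        elif name == "next":
            bends.append(_parse_point(child, ctx))
        elif name == "glyph" and child.get("class") == "cardinality":
            text = None
            for sub in child:
                if isinstance(sub.tag, str) and _localname(sub) == "label":
                    text = sub.get("text")
            try:
                cardinality = int(text)
            except (TypeError, ValueError):
                raise SbgnFormatError(
                    f"cardinality glyph on arc {aid} has non-integer "
                    f"label {text!r}")
        else:
            ledger.append((aid, etree.tostring(child, encoding="unicode")))
    return Arc(id=aid, cls=cls, source=src, target=tgt,
               start=start, end=end, bends=bends, cardinality=cardinality)


def read_map(source: Source) -> SbgnDocument:
    """Parse an SBGN-ML document from a path, bytes or binary stream."""
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif hasattr(source, "read"):
            root = etree.parse(source).getroot()
        else:
            root = etree.parse(os.fspath(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise SbgnFormatError(f"malformed XML: {exc}") from exc

    qname = etree.QName(root)
    if qname.localname != "sbgn":
        raise SbgnFormatError(f"root element is <{qname.localname}>, expected <sbgn>")
    namespace = qname.namespace or DEFAULT_NAMESPACE

    map_el = None
    for child in root:
        if isinstance(child.tag, str) and _localname(child) == "map":
            map_el = child
            break
    if map_el is None:
        raise SbgnFormatError("document has no <map> element")

    language = Language.from_token(map_el.get("language", ""))

    ledger: list[tuple[str, str]] = []
    glyphs: list[Glyph] = []
    arcs: list[Arc] = []
    notes = None
    for child in map_el:
        if not isinstance(child.tag, str):
            continue
        name = _localname(child)
        if name == "glyph":
            glyphs.append(_parse_glyph(child, ledger))
        elif name == "arc":
            arcs.append(_parse_arc(child, ledger))
        elif name == "notes":
            notes = "".join(child.itertext()).strip() or None
        else:
            ledger.append(("", etree.tostring(child, encoding="unicode")))

    sbgn_map = SbgnMap(language=language, glyphs=glyphs, arcs=arcs, notes=notes)
    return SbgnDocument(map=sbgn_map, namespace=namespace, unrecognized=ledger)


# ---------------------------------------------------------------------------
# Writing

def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips through float()."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _emit_glyph(parent, g: Glyph, nsmap_ns: str) -> None:
    el = etree.SubElement(parent, f"{{{nsmap_ns}}}glyph",
                          {"id": g.id, "class": g.cls})
    if g.compartment_ref is not None:
        el.set("compartmentRef", g.compartment_ref)
    if g.orientation is not None:
        el.set("orientation", g.orientation)
    if g.label is not None:
        etree.SubElement(el, f"{{{nsmap_ns}}}label", {"text": g.label})
    if g.clone:
        etree.SubElement(el, f"{{{nsmap_ns}}}clone")
    etree.SubElement(el, f"{{{nsmap_ns}}}bbox",
                     {"x": _fmt(g.bbox.x), "y": _fmt(g.bbox.y),
                      "w": _fmt(g.bbox.w), "h": _fmt(g.bbox.h)})
    for child in g.children:
        _emit_glyph(el, child, nsmap_ns)
    for p in g.ports:
        etree.SubElement(el, f"{{{nsmap_ns}}}port",
                         {"id": p.id, "x": _fmt(p.x), "y": _fmt(p.y)})


def _emit_arc(parent, a: Arc, ns: str) -> None:
    el = etree.SubElement(parent, f"{{{ns}}}arc",
                          {"id": a.id, "class": a.cls,
                           "source": a.source, "target": a.target})
    if a.cardinality is not None:
        card = etree.SubElement(el, f"{{{ns}}}glyph",
                                {"id": f"{a.id}.card", "class": "cardinality"})
        etree.SubElement(card, f"{{{ns}}}label", {"text": str(a.cardinality)})
        etree.SubElement(card, f"{{{ns}}}bbox",
                         {"x": "0", "y": "0", "w": "0", "h": "0"})
    etree.SubElement(el, f"{{{ns}}}start",
                     {"x": _fmt(a.start[0]), "y": _fmt(a.start[1])})
    for bend in a.bends:
        etree.SubElement(el, f"{{{ns}}}next",
                         {"x": _fmt(bend[0]), "y": _fmt(bend[1])})
    etree.SubElement(el, f"{{{ns}}}end",
                     {"x": _fmt(a.end[0]), "y": _fmt(a.end[1])})


def document_bytes(doc: SbgnDocument) -> bytes:
    """Serialise a document to SBGN-ML bytes (refuses unresolved references)."""
    dangling = [v for v in validate_map(doc.map)
                if v.code == "unresolved-reference"]
    if dangling:
        raise UnresolvedReferenceError(
            "refusing to write map with unresolved references: "
            + "; ".join(sorted(f"{v.ref}: {v.message}" for v in dangling)),
            ids=[v.ref for v in dangling])

    ns = doc.namespace or DEFAULT_NAMESPACE
    root = etree.Element(f"{{{ns}}}sbgn", nsmap={None: ns})
    map_el = etree.SubElement(root, f"{{{ns}}}map",
                              {"language": doc.map.language.value})
    if doc.map.notes:
        notes = etree.SubElement(map_el, f"{{{ns}}}notes")
        notes.text = doc.map.notes
    for g in doc.map.glyphs:
        _emit_glyph(map_el, g, ns)
    for a in doc.map.arcs:
        _emit_arc(map_el, a, ns)
    # re-emit preserved unknown fragments under the map element, after
    # everything else, so no recorded information is lost
    for _parent, fragment in doc.unrecognized:
        try:
            map_el.append(etree.fromstring(fragment))
        except etree.XMLSyntaxError:
            pass
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def write_map(doc: SbgnDocument, sink: Union[str, os.PathLike, BinaryIO]) -> None:
    """Write a document to a path or binary stream as SBGN-ML."""
    data = document_bytes(doc)
    if hasattr(sink, "write"):
        sink.write(data)
    else:
        with open(os.fspath(sink), "wb") as fh:
            fh.write(data)


# ---------------------------------------------------------------------------
# Layout export

def apply_layout(doc: SbgnDocument,
                 positions: dict[str, tuple[float, float]]) -> SbgnDocument:
    """Return a copy of ``doc`` with named glyphs translated to new centers.

    Each glyph named in ``positions`` is moved so its bbox center equals
    the given point (extent unchanged); its ports and sub-glyphs move by
    the same delta.  Arc endpoints attached to a moved glyph (directly or
    via one of its ports) are translated by that glyph's delta; other
    geometry is untouched.
    """
    new_doc = copy.deepcopy(doc)
    index = new_doc.map.glyph_index()
    unknown = sorted(set(positions) - set(index))
    if unknown:
        raise UnresolvedReferenceError(
            f"apply_layout: unknown glyph ids: {', '.join(unknown)}",
            ids=unknown)

    deltas: dict[str, tuple[float, float]] = {}

    def shift(g: Glyph, dx: float, dy: float) -> None:
        g.bbox = BBox(g.bbox.x + dx, g.bbox.y + dy, g.bbox.w, g.bbox.h)
        g.ports = [Port(p.id, p.x + dx, p.y + dy) for p in g.ports]
        for child in g.children:
            shift(child, dx, dy)

    for gid, (cx, cy) in positions.items():
        g = index[gid]
        ox, oy = glyph_center(g)
        dx, dy = cx - ox, cy - oy
        shift(g, dx, dy)
        deltas[gid] = (dx, dy)

    # endpoint id -> delta of its owning glyph
    port_owner = {pid: g.id for pid, g in new_doc.map.port_owner_index().items()}

    def endpoint_delta(ref: str) -> tuple[float, float]:
        gid = port_owner.get(ref, ref)
        return deltas.get(gid, (0.0, 0.0))

    for a in new_doc.map.arcs:
        sdx, sdy = endpoint_delta(a.source)
        a.start = (a.start[0] + sdx, a.start[1] + sdy)
        edx, edy = endpoint_delta(a.target)
        a.end = (a.end[0] + edx, a.end[1] + edy)
    return new_doc
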