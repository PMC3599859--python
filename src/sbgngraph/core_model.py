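"""Domain types for SBGN maps and the per-language class catalog.

The Systems Biology Graphical Notation (SBGN) is split into three
complementary languages — Process Description (PD), Entity Relationship
(ER) and Activity Flow (AF) — each with its own reference card of legal
glyph (node) and arc (edge) classes.  This module holds the in-memory
representation of a map (glyphs with bounding boxes, ports and nested
sub-glyphs; arcs with geometry) and structural validation against the
catalog: class legality, id uniqueness and reference resolution.

Class tokens are the lower-case, space-separated strings used by SBGN-ML
itself (e.g. ``"necessary stimulation"``); the catalog is shipped as data
(``data/catalog.json``) so reference-card updates are edits, not releases.
Semantic (rule-based) validation beyond class/reference legality is out of
scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterator, Optional

from .errors import CatalogError

__all__ = [
    "Language",
    "BBox",
    "Port",
    "Glyph",
    "Arc",
    "SbgnMap",
    "Violation",
    "allowed_classes",
    "validate_map",
    "glyph_center",
    "maps_equivalent",
    "AUX_UNIT_CLASSES",
    "CONTAINER_CLASSES",
]

#: Glyph classes that only ever occur as decorations attached to a parent
#: glyph or arc (they become attributes, not nodes, in the property graph).
AUX_UNIT_CLASSES = frozenset(
    {"state variable", "unit of information", "cardinality",
     "existence", "location", "variable value"}
)

#: Container / annotation glyph classes the simplifier removes.
CONTAINER_CLASSES = frozenset({"compartment", "tag", "submap", "terminal"})


class Language(str, Enum):
    """The three complementary SBGN languages."""

    PD = "process description"
    ER = "entity relationship"
    AF = "activity flow"

    @classmethod
    def from_token(cls, token: str) -> "Language":
        for member in cls:
            if member.value == token:
                return member
        raise CatalogError(f"unknown SBGN language token: {token!r}")


@dataclass(frozen=True)
class BBox:
    """Axis-aligned bounding box, top-left corner + extent, in map units."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w < 0 or self.h < 0:
            raise ValueError(f"negative extent: w={self.w}, h={self.h}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def intersects(self, other: "BBox") -> bool:
        """Strict interior overlap (shared edges do not count)."""
        return (self.x < other.x + other.w and other.x < self.x + self.w
                and self.y < other.y + other.h and other.y < self.y + self.h)


@dataclass(frozen=True)
class Port:
    """Named attachment point on a glyph."""

    id: str
    x: float
    y: float


@dataclass
class Glyph:
    """A typed SBGN node: entity pool, process, container, logic operator
    or auxiliary unit, with geometry, label, ports and nested sub-glyphs."""

    id: str
    cls: str
    bbox: BBox
    label: Optional[str] = None
    compartment_ref: Optional[str] = None
    ports: list[Port] = field(default_factory=list)
    children: list["Glyph"] = field(default_factory=list)
    clone: bool = False
    orientation: Optional[str] = None

    def walk(self) -> Iterator["Glyph"]:
        """Depth-first iteration over this glyph and all nested sub-glyphs."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Arc:
    """A typed SBGN edge between glyphs or ports, with polyline geometry."""

    id: str
    cls: str
    source: str
    target: str
    start: tuple[float, float] = (0.0, 0.0)
    end: tuple[float, float] = (0.0, 0.0)
    bends: list[tuple[float, float]] = field(default_factory=list)
    cardinality: Optional[int] = None


@dataclass
class SbgnMap:
    """A parsed diagram: language plus glyph and arc collections."""

    language: Language
    glyphs: list[Glyph] = field(default_factory=list)
    arcs: list[Arc] = field(default_factory=list)
    notes: Optional[str] = None

    def iter_glyphs(self) -> Iterator[Glyph]:
        """All glyphs including nested sub-glyphs, document order."""
        for g in self.glyphs:
            yield from g.walk()

    def glyph_index(self) -> dict[str, Glyph]:
        return {g.id: g for g in self.iter_glyphs()}

    def port_owner_index(self) -> dict[str, Glyph]:
        """Map port id -> owning glyph."""
        owners: dict[str, Glyph] = {}
        for g in self.iter_glyphs():
            for p in g.ports:
                owners[p.id] = g
        return owners


# ---------------------------------------------------------------------------
# Catalog

def _load_catalog() -> dict[str, dict[str, frozenset[str]]]:
    raw = json.loads(
        resources.files("sbgngraph").joinpath("data/catalog.json").read_text()
    )
    return {
        lang: {kind: frozenset(classes) for kind, classes in kinds.items()}
        for lang, kinds in raw.items()
        if not lang.startswith("_")
    }


_CATALOG = _load_catalog()


def allowed_classes(language: Language, kind: str) -> frozenset[str]:
    """Legal class tokens for ``language`` and ``kind`` ("glyph" or "arc")."""
    if not isinstance(language, Language):
        language = Language.from_token(str(language))
    try:
        return _CATALOG[language.value][kind]
    except KeyError:
        raise CatalogError(f"unknown catalog kind: {kind!r} (use 'glyph' or 'arc')")


# ---------------------------------------------------------------------------
# Validation

@dataclass(frozen=True)
class Violation:
    """One structural problem found by :func:`validate_map`."""

    code: str
    ref: str
    message: str
    severity: str = "error"  # "error" | "warning"


def _check_ids(map: SbgnMap) -> list[Violation]:
    out = []
    seen: set[str] = set()
    for g in map.iter_glyphs():
        if g.id in seen:
            out.append(Violation("duplicate-id", g.id,
                                 f"glyph id {g.id!r} occurs more than once"))
        seen.add(g.id)
    for a in map.arcs:
        if a.id in seen:
            out.append(Violation("duplicate-id", a.id,
                                 f"arc id {a.id!r} collides with another element"))
        seen.add(a.id)
    return out


def validate_map(map: SbgnMap) -> list[Violation]:
    """Check all structural invariants of a map; report, never raise.

    Returns an empty list iff ids are unique, every reference resolves,
    every class is legal for the map's language, compartment references
    name compartment glyphs, and sub-glyph nesting is at most one level
    deep (deeper nesting is a warning, not an error).
    """
    violations = _check_ids(map)
    glyph_classes = allowed_classes(map.language, "glyph")
    arc_classes = allowed_classes(map.language, "arc")
    index = map.glyph_index()
    ports = map.port_owner_index()

    for g in map.iter_glyphs():
        if g.cls not in glyph_classes:
            violations.append(Violation(
                "class-not-in-language", g.id,
                f"glyph class {g.cls!r} is not in the {map.language.value} catalog"))
        if g.compartment_ref is not None:
            ref = index.get(g.compartment_ref)
            if ref is None:
                violations.append(Violation(
                    "unresolved-reference", g.id,
                    f"compartmentRef {g.compartment_ref!r} names no glyph"))
            elif ref.cls != "compartment":
                violations.append(Violation(
                    "bad-compartment-ref", g.id,
                    f"compartmentRef {g.compartment_ref!r} is a {ref.cls!r}, "
                    "not a compartment"))

    # nesting depth: children of children are tolerated with a warning
    for g in map.glyphs:
        for child in g.children:
            for grandchild in child.children:
                violations.append(Violation(
                    "deep-nesting", grandchild.id,
                    f"glyph {grandchild.id!r} nested more than one level deep",
                    severity="warning"))

    for a in map.arcs:
        if a.cls not in arc_classes:
            violations.append(Violation(
                "class-not-in-language", a.id,
                f"arc class {a.cls!r} is not in the {map.language.value} catalog"))
        for role, ref in (("source", a.source), ("target", a.target)):
            if ref not in index and ref not in ports:
                violations.append(Violation(
                    "unresolved-reference", a.id,
                    f"arc {role} {ref!r} resolves to no glyph or port"))
        if a.cardinality is not None and a.cardinality < 1:
            violations.append(Violation(
                "bad-cardinality", a.id,
                f"cardinality must be >= 1, got {a.cardinality}"))
    return violations


def glyph_center(g: Glyph) -> tuple[float, float]:
    """Center point of a glyph's bounding box."""
    return g.bbox.center


# ---------------------------------------------------------------------------
# Semantic equality (round-trip oracle support)

_GEOM_TOL = 1e-9


def _points_close(p: tuple[float, float], q: tuple[float, float]) -> bool:
    return math.isclose(p[0], q[0], abs_tol=_GEOM_TOL) and \
        math.isclose(p[1], q[1], abs_tol=_GEOM_TOL)


def _glyphs_equivalent(a: Glyph, b: Glyph) -> bool:
    if (a.id, a.cls, a.label, a.compartment_ref, a.clone, a.orientation) != \
            (b.id, b.cls, b.label, b.compartment_ref, b.clone, b.orientation):
        return False
    for u, v in (("x", "x"), ("y", "y"), ("w", "w"), ("h", "h")):
        if not math.isclose(getattr(a.bbox, u), getattr(b.bbox, v),
                            abs_tol=_GEOM_TOL):
            return False
    if len(a.ports) != len(b.ports) or len(a.children) != len(b.children):
        return False
    for pa, pb in zip(a.ports, b.ports):
        if pa.id != pb.id or not _points_close((pa.x, pa.y), (pb.x, pb.y)):
            return False
    return all(_glyphs_equivalent(ca, cb) for ca, cb in zip(a.children, b.children))


def maps_equivalent(a: SbgnMap, b: SbgnMap) -> bool:
    """Semantic equality: same language, ids, classes, labels, clone flags
    and geometry within 1e-9; element order must agree (document order is
    meaningful in SBGN-ML)."""
    if a.language != b.language:
        return False
    if len(a.glyphs) != len(b.glyphs) or len(a.arcs) != len(b.arcs):
        return False
    if not all(_glyphs_equivalent(ga, gb) for ga, gb in zip(a.glyphs, b.glyphs)):
        return False
    for aa, ab in zip(a.arcs, b.arcs):
        if (aa.id, aa.cls, aa.source, aa.target, aa.cardinality) != \
                (ab.id, ab.cls, ab.source, ab.target, ab.cardinality):
            return False
        if not (_points_close(aa.start, ab.start) and _points_close(aa.end, ab.end)):
            return False
        if len(aa.bends) != len(ab.bends) or \
                not all(_points_close(p, q) for p, q in zip(aa.bends, ab.bends)):
            return False
    return True
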