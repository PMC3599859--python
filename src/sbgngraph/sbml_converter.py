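"""Generate an SBGN Process Description map from an SBML model.

SBML stores the biochemistry (species, reactions, modifiers,
compartments) but not a diagram; this module maps it onto PD glyphs and
arcs and lays the result out deterministically so the map can be
rendered or analysed immediately.

Mapping rules (``ConversionRules``):

* species -> entity-pool glyph; the SBO term picks the glyph class
  (simple chemical for small-molecule terms, macromolecule by default);
* reaction -> one process glyph; reactants/products -> consumption/
  production arcs (stoichiometry > 1 becomes arc cardinality);
* modifier -> arc whose class follows the modifier's SBO term
  (catalysis for catalysts, inhibition for inhibitors, stimulation for
  stimulators, otherwise modulation);
* SBML compartment -> compartment glyph; species glyphs carry a
  ``compartmentRef``;
* reversible reactions stay a single process; reversibility is recorded
  as a unit-of-information decoration (PD has no reversible-process
  glyph).

Species used by many reactions can either stay one shared glyph
(default) or, above a configurable ``clone_threshold``, be duplicated
per usage with clone markers — the common SBGN practice for cofactors.

SBML Levels 2 and 3 are read with a level/version-tolerant XML parser.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Union

from lxml import etree

from .core_model import Arc, BBox, Glyph, Language, SbgnMap
from .errors import SbgnFormatError, UnresolvedReferenceError

__all__ = ["ConversionRules", "LayoutConfig", "SbmlModel", "read_sbml",
           "convert", "auto_layout"]

_SPECIES_SBO_CLASS = {
    "SBO:0000247": "simple chemical",
    "SBO:0000299": "simple chemical",
    "SBO:0000245": "macromolecule",
    "SBO:0000252": "macromolecule",
    "SBO:0000250": "nucleic acid feature",
    "SBO:0000251": "nucleic acid feature",
    "SBO:0000253": "complex",
    "SBO:0000285": "unspecified entity",
}

_MODIFIER_SBO_CLASS = {
    "SBO:0000013": "catalysis",
    "SBO:0000460": "catalysis",
    "SBO:0000461": "catalysis",
    "SBO:0000020": "inhibition",
    "SBO:0000206": "inhibition",
    "SBO:0000207": "inhibition",
    "SBO:0000459": "stimulation",
    "SBO:0000021": "stimulation",
}


@dataclass(frozen=True)
class ConversionRules:
    """SBO-driven class mapping plus the species-duplication policy."""

    species_class: dict = field(default_factory=lambda: dict(_SPECIES_SBO_CLASS))
    default_species_class: str = "macromolecule"
    modifier_class: dict = field(default_factory=lambda: dict(_MODIFIER_SBO_CLASS))
    default_modifier_class: str = "modulation"
    #: species participating in more than this many reactions are duplicated
    #: with clone markers; None keeps one shared glyph per species
    clone_threshold: Optional[int] = None


@dataclass(frozen=True)
class LayoutConfig:
    """Grid constants for the layered layout, in map units."""

    column_gap: float = 120.0
    row_gap: float = 80.0
    glyph_w: float = 80.0
    glyph_h: float = 40.0
    margin: float = 20.0


# ---------------------------------------------------------------------------
# SBML reading (lxml, level/version tolerant)

@dataclass
class _Reaction:
    id: str
    reactants: list[tuple[str, float]]
    products: list[tuple[str, float]]
    modifiers: list[tuple[str, Optional[str]]]
    reversible: bool


@dataclass
class SbmlModel:
    """The slice of an SBML model the converter needs."""

    id: str
    compartments: list[str]
    species: list[tuple[str, Optional[str], Optional[str], Optional[str]]]
    # (id, name, compartment, sboTerm)
    reactions: list[_Reaction]


def _children(el, name: str):
    return [c for c in el.iter() if isinstance(c.tag, str)
            and etree.QName(c).localname == name]


def read_sbml(source: Union[str, bytes]) -> SbmlModel:
    """Parse an SBML Level 2/3 document from a path or bytes."""
    try:
        root = etree.fromstring(source) if isinstance(source, bytes) \
            else etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise SbgnFormatError(f"malformed SBML XML: {exc}") from exc
    if etree.QName(root).localname != "sbml":
        raise SbgnFormatError("root element is not <sbml>")
    level = root.get("level")
    if level not in ("2", "3"):
        raise SbgnFormatError(f"unsupported SBML level {level!r} "
                              "(levels 2 and 3 are supported)")
    models = [c for c in root if isinstance(c.tag, str)
              and etree.QName(c).localname == "model"]
    if not models:
        raise SbgnFormatError("SBML document has no <model>")
    model_el = models[0]

    compartments = [c.get("id") for c in _children(model_el, "compartment")]
    species = [(s.get("id"), s.get("name"), s.get("compartment"),
                s.get("sboTerm")) for s in _children(model_el, "species")]
    sids = [s[0] for s in species]
    if len(set(sids)) != len(sids):
        raise SbgnFormatError("duplicate SBML species ids")

    reactions = []
    for r_el in _children(model_el, "reaction"):
        def refs(list_name: str):
            out = []
            for lst in _children(r_el, list_name):
                for ref in _children(lst, "speciesReference"):
                    stoich = float(ref.get("stoichiometry", "1") or "1")
                    out.append((ref.get("species"), stoich))
            return out

        modifiers = []
        for lst in _children(r_el, "listOfModifiers"):
            for ref in _children(lst, "modifierSpeciesReference"):
                modifiers.append((ref.get("species"), ref.get("sboTerm")))
        reactions.append(_Reaction(
            id=r_el.get("id"),
            reactants=refs("listOfReactants"),
            products=refs("listOfProducts"),
            modifiers=modifiers,
            reversible=(r_el.get("reversible", "true") == "true"),
        ))
    return SbmlModel(id=model_el.get("id") or "model",
                     compartments=compartments, species=species,
                     reactions=reactions)


# ---------------------------------------------------------------------------
# Conversion

def convert(model: Union[SbmlModel, str, bytes],
            rules: ConversionRules = ConversionRules()) -> SbgnMap:
    """Map an SBML model onto an SBGN PD map (geometry left to
    :func:`auto_layout`)."""
    if not isinstance(model, SbmlModel):
        model = read_sbml(model)
    if not model.species and not model.reactions:
        raise SbgnFormatError("model has neither species nor reactions")

    species_info = {sid: (name, comp, sbo)
                    for sid, name, comp, sbo in model.species}
    for r in model.reactions:
        for sid, _ in r.reactants + r.products:
            if sid not in species_info:
                raise UnresolvedReferenceError(
                    f"reaction {r.id!r} references missing species {sid!r}",
                    ids=[sid])
        for sid, _ in r.modifiers:
            if sid not in species_info:
                raise UnresolvedReferenceError(
                    f"reaction {r.id!r} references missing species {sid!r}",
                    ids=[sid])

    usage_count: dict[str, int] = {sid: 0 for sid in species_info}
    for r in model.reactions:
        for sid in {s for s, _ in r.reactants} | {s for s, _ in r.products} \
                | {s for s, _ in r.modifiers}:
            usage_count[sid] += 1

    glyphs: list[Glyph] = []
    arcs: list[Arc] = []
    zero = BBox(0, 0, 0, 0)

    for comp in model.compartments:
        glyphs.append(Glyph(id=comp, cls="compartment", label=comp, bbox=zero))

    def species_cls(sid: str) -> str:
        sbo = species_info[sid][2]
        return rules.species_class.get(sbo, rules.default_species_class)

    cloned = {sid for sid, n in usage_count.items()
              if rules.clone_threshold is not None
              and n > rules.clone_threshold}
    shared_emitted: set[str] = set()
    clone_serial: dict[str, int] = {}

    def species_glyph(sid: str) -> str:
        """Emit (or reuse) the glyph for one species usage; return its id."""
        name, comp, _sbo = species_info[sid]
        label = name or sid
        if sid in cloned:
            clone_serial[sid] = clone_serial.get(sid, 0) + 1
            gid = f"{sid}.use{clone_serial[sid]}"
            glyphs.append(Glyph(id=gid, cls=species_cls(sid), label=label,
                                bbox=zero, compartment_ref=comp, clone=True))
            return gid
        if sid not in shared_emitted:
            glyphs.append(Glyph(id=sid, cls=species_cls(sid), label=label,
                                bbox=zero, compartment_ref=comp))
            shared_emitted.add(sid)
        return sid

    for sid, *_ in model.species:
        if usage_count[sid] == 0:
            species_glyph(sid)

    for r in model.reactions:
        pid = f"{r.id}.proc"
        children = []
        if r.reversible:
            children.append(Glyph(id=f"{pid}.rev", cls="unit of information",
                                  label="reversible", bbox=zero))
        glyphs.append(Glyph(id=pid, cls="process", label=r.id, bbox=zero,
                            children=children))
        for i, (sid, stoich) in enumerate(r.reactants):
            gid = species_glyph(sid)
            arcs.append(Arc(id=f"{r.id}.c{i}", cls="consumption",
                            source=gid, target=pid,
                            cardinality=int(stoich) if stoich > 1 else None))
        for i, (sid, stoich) in enumerate(r.products):
            gid = species_glyph(sid)
            arcs.append(Arc(id=f"{r.id}.p{i}", cls="production",
                            source=pid, target=gid,
                            cardinality=int(stoich) if stoich > 1 else None))
        for i, (sid, sbo) in enumerate(r.modifiers):
            gid = species_glyph(sid)
            arcs.append(Arc(id=f"{r.id}.m{i}",
                            cls=rules.modifier_class.get(
                                sbo, rules.default_modifier_class),
                            source=gid, target=pid))
    return SbgnMap(language=Language.PD, glyphs=glyphs, arcs=arcs)


# ---------------------------------------------------------------------------
# Layout

def auto_layout(map: SbgnMap, config: LayoutConfig = LayoutConfig()) -> SbgnMap:
    """Deterministic layered left-to-right layout; returns a new map.

    Non-compartment glyphs are placed on a grid: reactants in the left
    column, processes (and modifiers, in their own rows) in the middle,
    products on the right; reactions stack vertically, grouped into one
    vertical band per compartment so compartment boxes never overlap
    each other.  Compartment glyphs become enclosing boxes around their
    members; all other glyph pairs are disjoint by construction (one
    grid cell each).
    """
    out = copy.deepcopy(map)
    cfg = config
    glyph_by_id = out.glyph_index()
    compartments = [g for g in out.glyphs if g.cls == "compartment"]
    others = [g for g in out.glyphs if g.cls != "compartment"]

    # column per glyph: first role seen (reactant 0 / process+modifier 1 /
    # product 2); glyphs never touched by an arc go to column 0
    col: dict[str, int] = {}
    for a in out.arcs:
        if a.cls == "consumption":
            col.setdefault(a.source, 0)
            col.setdefault(a.target, 1)
        elif a.cls == "production":
            col.setdefault(a.source, 1)
            col.setdefault(a.target, 2)
        else:
            col.setdefault(a.source, 1)
            col.setdefault(a.target, 1)
    for g in others:
        col.setdefault(g.id, 0)

    # band per compartment (document order), plus one for unassigned glyphs
    band_order = [c.id for c in compartments] + [None]
    band_index = {b: i for i, b in enumerate(band_order)}

    def band_of(g: Glyph):
        ref = g.compartment_ref
        return ref if ref in band_index else None

    # assign each glyph the next free row slot of its (band, column)
    next_slot: dict[tuple, int] = {}
    band_rows: dict[object, int] = {b: 0 for b in band_order}
    placement: dict[str, tuple[object, int, int]] = {}
    for g in others:
        b = band_of(g)
        c = col[g.id]
        slot = next_slot.get((b, c), 0)
        next_slot[(b, c)] = slot + 1
        placement[g.id] = (b, c, slot)
        band_rows[b] = max(band_rows[b], slot + 1)

    # vertical offset of each band
    band_y: dict[object, float] = {}
    y = cfg.margin
    for b in band_order:
        band_y[b] = y
        rows = max(band_rows[b], 1 if b is not None else band_rows[b])
        y += rows * cfg.row_gap + cfg.row_gap  # inter-band gap

    for g in others:
        b, c, slot = placement[g.id]
        x = cfg.margin + c * cfg.column_gap
        gy = band_y[b] + slot * cfg.row_gap
        w, h = (cfg.glyph_w, cfg.glyph_h)
        if g.cls == "process":
            w = h = min(cfg.glyph_h, 30.0)
            x += (cfg.glyph_w - w) / 2.0  # center processes in their column
        g.bbox = BBox(x, gy, w, h)

    # compartments enclose their members (empty ones get a unit box in
    # their own band)
    pad = cfg.margin / 2.0
    for comp in compartments:
        members = [g for g in others if g.compartment_ref == comp.id]
        if members:
            x0 = min(g.bbox.x for g in members) - pad
            y0 = min(g.bbox.y for g in members) - pad
            x1 = max(g.bbox.x + g.bbox.w for g in members) + pad
            y1 = max(g.bbox.y + g.bbox.h for g in members) + pad
            comp.bbox = BBox(x0, y0, x1 - x0, y1 - y0)
        else:
            comp.bbox = BBox(cfg.margin, band_y[comp.id],
                             cfg.glyph_w, cfg.glyph_h)

    # nested decorations (units of information) ride on their parent
    for g in out.iter_glyphs():
        if g.children:
            for i, child in enumerate(g.children):
                child.bbox = BBox(g.bbox.x + 4 + 30 * i, g.bbox.y - 8, 28, 12)

    # arc geometry: straight center-to-center segments
    for a in out.arcs:
        src = glyph_by_id.get(a.source)
        tgt = glyph_by_id.get(a.target)
        if src is not None:
            a.start = src.bbox.center
        if tgt is not None:
            a.end = tgt.bbox.center
    return out
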