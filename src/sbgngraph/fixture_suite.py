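"""Deterministic synthetic SBGN-ML test maps.

The suite provides, per language, one minimal map per glyph class and one
per arc class, plus composite cases (compartment containment, complex
nesting, a clone pair), so that together the three suites exercise the
complete reference-card catalog.  It emulates, at desk scale, the public
libSBGN render-comparison suite (8 AF / 18 ER / 27 PD files); suite sizes
here are derived from the catalog rather than forced to match those
published counts, which the manifest records alongside ours for
comparison.

A toy linear metabolic chain (pyruvate -> ... -> succinate, optionally
with clone-marked ATP/ADP cofactors on every reaction) stands in for a
full central-plant-metabolism map in the analysis examples.

All generation is deterministic: geometry is a fixed grid, and the same
case spec always yields byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core_model import (
    AUX_UNIT_CLASSES, Arc, BBox, Glyph, Language, SbgnMap, allowed_classes,
)
from .errors import CatalogError
from .sbgnml_io import SbgnDocument

__all__ = ["CaseSpec", "generate_case", "generate_suite", "suite_manifest",
           "generate_toy_metabolism", "generate_random_sbml",
           "LIBSBGN_REFERENCE_SUITE_SIZES"]

#: Published sizes of the libSBGN render-comparison suite, for the manifest.
LIBSBGN_REFERENCE_SUITE_SIZES = {"activity flow": 8, "entity relationship": 18,
                                 "process description": 27}

_GW, _GH = 80.0, 40.0  # default glyph extent on the fixture grid
_GAP = 140.0

#: preferred endpoint glyph class for arc-focused cases, per language
_ARC_ENDPOINTS = {
    Language.PD: ("macromolecule", "process"),
    Language.ER: ("macromolecule", "interaction"),
    Language.AF: ("biological activity", "biological activity"),
}

#: auxiliary-unit classes need a parent glyph to sit on
_AUX_PARENT = {
    Language.PD: "macromolecule",
    Language.ER: "macromolecule",
    Language.AF: "biological activity",
}


@dataclass(frozen=True)
class CaseSpec:
    """One synthetic test case: a language plus the class under focus."""

    language: Language
    kind: str          # "glyph" | "arc" | "composite"
    focus: str
    seed: int = 0
    origin: tuple[float, float] = (20.0, 20.0)

    @property
    def name(self) -> str:
        lang = {"process description": "pd", "entity relationship": "er",
                "activity flow": "af"}[self.language.value]
        return f"{lang}_{self.kind}_{self.focus.replace(' ', '-')}"


def _box(col: int, row: int, origin=(20.0, 20.0),
         w: float = _GW, h: float = _GH) -> BBox:
    return BBox(origin[0] + col * _GAP, origin[1] + row * _GAP, w, h)


def _glyph_case(spec: CaseSpec) -> SbgnMap:
    cls = spec.focus
    glyphs: list[Glyph] = []
    if cls in AUX_UNIT_CLASSES:
        parent_cls = _AUX_PARENT[spec.language]
        child = Glyph(id="g1.a", cls=cls, bbox=BBox(30, 10, 30, 15),
                      label="P" if cls == "state variable" else "info")
        glyphs.append(Glyph(id="g1", cls=parent_cls, label="X",
                            bbox=_box(0, 0, spec.origin), children=[child]))
    elif cls == "terminal":
        child = Glyph(id="g1.t", cls="terminal", label="out",
                      bbox=BBox(30, 10, 30, 15), orientation="right")
        glyphs.append(Glyph(id="g1", cls="submap", label="module",
                            bbox=_box(0, 0, spec.origin, w=160, h=120),
                            children=[child]))
    else:
        glyphs.append(Glyph(id="g1", cls=cls, bbox=_box(0, 0, spec.origin),
                            label=None if cls in ("and", "or", "not",
                                                  "delay", "implicit xor")
                            else cls.upper()[:12]))
    return SbgnMap(language=spec.language, glyphs=glyphs)


def _arc_case(spec: CaseSpec) -> SbgnMap:
    src_cls, tgt_cls = _ARC_ENDPOINTS[spec.language]
    a = Glyph(id="g1", cls=src_cls, label="A", bbox=_box(0, 0, spec.origin))
    b = Glyph(id="g2", cls=tgt_cls, label="B", bbox=_box(2, 0, spec.origin))
    arc = Arc(id="a1", cls=spec.focus, source="g1", target="g2",
              start=a.bbox.center, end=b.bbox.center)
    return SbgnMap(language=spec.language, glyphs=[a, b], arcs=[arc])


def _composite_case(spec: CaseSpec) -> SbgnMap:
    lang = spec.language
    if spec.focus == "containment":
        comp_cls = "compartment" if "compartment" in \
            allowed_classes(lang, "glyph") else "submap"
        ent = _ARC_ENDPOINTS[lang][0]
        comp = Glyph(id="c1", cls=comp_cls, label="cytosol",
                     bbox=BBox(10, 10, 400, 200))
        inner = [Glyph(id="g1", cls=ent, label="A", bbox=_box(0, 0, (40, 60)),
                       compartment_ref="c1" if comp_cls == "compartment" else None),
                 Glyph(id="g2", cls=ent, label="B", bbox=_box(1, 0, (40, 60)),
                       compartment_ref="c1" if comp_cls == "compartment" else None)]
        arc_cls = {"process description": "stimulation",
                   "entity relationship": "modulation",
                   "activity flow": "positive influence"}[lang.value]
        arc = Arc(id="a1", cls=arc_cls, source="g1", target="g2",
                  start=inner[0].bbox.center, end=inner[1].bbox.center)
        return SbgnMap(language=lang, glyphs=[comp] + inner, arcs=[arc])
    if spec.focus == "nesting":
        member_cls = _ARC_ENDPOINTS[lang][0]
        outer_cls = "complex" if "complex" in allowed_classes(lang, "glyph") \
            else "submap"
        members = [Glyph(id=f"m{i}", cls=member_cls, label=f"SU{i}",
                         bbox=BBox(40 + 90 * i, 50, 70, 30))
                   for i in range(2)]
        outer = Glyph(id="cx1", cls=outer_cls, label="cplx",
                      bbox=BBox(20, 20, 240, 120), children=members)
        return SbgnMap(language=lang, glyphs=[outer])
    if spec.focus == "clones":
        ent = _ARC_ENDPOINTS[lang][0]
        glyphs = [Glyph(id=f"g{i}", cls=ent, label="ATP", clone=True,
                        bbox=_box(i, 0, spec.origin)) for i in range(2)]
        return SbgnMap(language=lang, glyphs=glyphs)
    raise CatalogError(f"unknown composite focus {spec.focus!r}")


def generate_case(spec: CaseSpec) -> SbgnDocument:
    """Minimal valid map exhibiting the focus class of ``spec``."""
    if spec.kind in ("glyph", "arc"):
        if spec.focus not in allowed_classes(spec.language, spec.kind):
            raise CatalogError(
                f"{spec.kind} class {spec.focus!r} is not legal in "
                f"{spec.language.value}")
        m = _glyph_case(spec) if spec.kind == "glyph" else _arc_case(spec)
    elif spec.kind == "composite":
        m = _composite_case(spec)
    else:
        raise CatalogError(f"unknown case kind {spec.kind!r}")
    return SbgnDocument(map=m)


def _suite_specs(language: Language) -> list[CaseSpec]:
    specs = [CaseSpec(language, "glyph", cls)
             for cls in sorted(allowed_classes(language, "glyph"))]
    specs += [CaseSpec(language, "arc", cls)
              for cls in sorted(allowed_classes(language, "arc"))]
    specs += [CaseSpec(language, "composite", focus)
              for focus in ("containment", "nesting", "clones")]
    return specs


def generate_suite(language: Language) -> list[tuple[CaseSpec, SbgnDocument]]:
    """One case per catalog glyph class and arc class, plus composites."""
    return [(spec, generate_case(spec)) for spec in _suite_specs(language)]


def suite_manifest() -> dict:
    """Case counts per language, with the published libSBGN suite sizes
    recorded for comparison (ours are catalog-derived, not file-identical)."""
    counts = {lang.value: len(_suite_specs(lang)) for lang in Language}
    return {
        "case_counts": counts,
        "total": sum(counts.values()),
        "libsbgn_reference_suite_sizes": dict(LIBSBGN_REFERENCE_SUITE_SIZES),
        "libsbgn_reference_total": sum(LIBSBGN_REFERENCE_SUITE_SIZES.values()),
    }


def generate_toy_metabolism(n_reactions: int = 3, cofactor_clones: bool = True,
                            seed: int = 0) -> SbgnDocument:
    """Linear PD chain emulating a central-metabolism map at desk scale.

    ``M0 -> p1 -> M1 -> ... -> pn -> Mn`` with M0 named "pyruvate" and Mn
    "succinate"; with ``cofactor_clones`` every process additionally
    consumes a clone-marked ATP and produces a clone-marked ADP.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    rng = random.Random(seed)
    names = ["pyruvate"] + [f"M{i}" for i in range(1, n_reactions)] + ["succinate"]
    glyphs: list[Glyph] = []
    arcs: list[Arc] = []
    for i, name in enumerate(names):
        glyphs.append(Glyph(id=f"m{i}", cls="simple chemical", label=name,
                            bbox=_box(2 * i, 0, (20, 20), w=60, h=60)))
    for r in range(1, n_reactions + 1):
        pid = f"p{r}"
        pbox = _box(2 * r - 1, 0, (20, 20), w=24, h=24)
        glyphs.append(Glyph(id=pid, cls="process", bbox=pbox))
        arcs.append(Arc(id=f"a{r}.in", cls="consumption",
                        source=f"m{r - 1}", target=pid,
                        start=glyphs[r - 1].bbox.center, end=pbox.center))
        arcs.append(Arc(id=f"a{r}.out", cls="production",
                        source=pid, target=f"m{r}",
                        start=pbox.center, end=_box(2 * r, 0, (20, 20),
                                                    w=60, h=60).center))
        if cofactor_clones:
            atp = Glyph(id=f"atp{r}", cls="simple chemical", label="ATP",
                        clone=True, bbox=_box(2 * r - 1, 1, (20, 20),
                                              w=50, h=50))
            adp = Glyph(id=f"adp{r}", cls="simple chemical", label="ADP",
                        clone=True, bbox=_box(2 * r, 1, (20, 20), w=50, h=50))
            glyphs += [atp, adp]
            arcs.append(Arc(id=f"a{r}.atp", cls="consumption",
                            source=atp.id, target=pid,
                            start=atp.bbox.center, end=pbox.center))
            arcs.append(Arc(id=f"a{r}.adp", cls="production",
                            source=pid, target=adp.id,
                            start=pbox.center, end=adp.bbox.center))
    notes = f"toy metabolic chain, seed={rng.randint(0, 10 ** 6)}"
    m = SbgnMap(language=Language.PD, glyphs=glyphs, arcs=arcs, notes=notes)
    return SbgnDocument(map=m)


# ---------------------------------------------------------------------------
# Random small SBML models (inputs for the SBML -> SBGN converter tests)

_MODIFIER_SBO = ["SBO:0000013", "SBO:0000020", "SBO:0000459", None]
_SPECIES_SBO = ["SBO:0000247", "SBO:0000245", None]


def generate_random_sbml(seed: int, max_species: int = 8,
                         max_reactions: int = 5) -> bytes:
    """A small random but deterministic SBML Level 3 model as XML bytes."""
    rng = random.Random(seed)
    n_species = rng.randint(2, max_species)
    n_reactions = rng.randint(1, max_reactions)
    n_comp = rng.randint(1, 2)
    comps = [f"comp{i}" for i in range(n_comp)]
    species = [(f"S{i}", rng.choice(comps), rng.choice(_SPECIES_SBO))
               for i in range(n_species)]

    lines = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
             'level="3" version="1">',
             f'  <model id="random_{seed}">',
             "    <listOfCompartments>"]
    for c in comps:
        lines.append(f'      <compartment id="{c}" constant="true"/>')
    lines.append("    </listOfCompartments>")
    lines.append("    <listOfSpecies>")
    for sid, comp, sbo in species:
        sbo_attr = f' sboTerm="{sbo}"' if sbo else ""
        lines.append(f'      <species id="{sid}" compartment="{comp}"'
                     f'{sbo_attr} hasOnlySubstanceUnits="false" '
                     'boundaryCondition="false" constant="false"/>')
    lines.append("    </listOfSpecies>")
    lines.append("    <listOfReactions>")
    ids = [s[0] for s in species]
    for r in range(n_reactions):
        k_in = rng.randint(1, min(3, n_species))
        k_out = rng.randint(1, min(3, n_species))
        reactants = rng.sample(ids, k_in)
        products = rng.sample(ids, k_out)
        modifiers = [(m, rng.choice(_MODIFIER_SBO))
                     for m in rng.sample(ids, rng.randint(0, 2))]
        rev = "true" if rng.random() < 0.2 else "false"
        lines.append(f'      <reaction id="R{r}" reversible="{rev}" fast="false">')
        lines.append("        <listOfReactants>")
        for s in reactants:
            stoich = rng.choice([1, 1, 1, 2])
            lines.append(f'          <speciesReference species="{s}" '
                         f'stoichiometry="{stoich}" constant="true"/>')
        lines.append("        </listOfReactants>")
        lines.append("        <listOfProducts>")
        for s in products:
            lines.append(f'          <speciesReference species="{s}" '
                         'stoichiometry="1" constant="true"/>')
        lines.append("        </listOfProducts>")
        if modifiers:
            lines.append("        <listOfModifiers>")
            for m, sbo in modifiers:
                sbo_attr = f' sboTerm="{sbo}"' if sbo else ""
                lines.append(f'          <modifierSpeciesReference '
                             f'species="{m}"{sbo_attr}/>')
            lines.append("        </listOfModifiers>")
        lines.append("      </reaction>")
    lines.append("    </listOfReactions>")
    lines.append("  </model>")
    lines.append("</sbml>")
    return "\n".join(lines).encode()
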