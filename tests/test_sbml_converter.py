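"""SBML -> SBGN PD conversion and automatic layout."""

import pytest

from sbgngraph import (
    ConversionRules, Language, auto_layout, convert, generate_random_sbml,
    validate_map,
)
from sbgngraph.errors import SbgnFormatError, UnresolvedReferenceError
from sbgngraph.sbml_converter import read_sbml

SIMPLE = b"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="m">
    <listOfCompartments>
      <compartment id="cell" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="S1" compartment="cell" sboTerm="SBO:0000247"/>
      <species id="S2" compartment="cell"/>
      <species id="P" compartment="cell"/>
      <species id="E" compartment="cell"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R1" reversible="false">
        <listOfReactants>
          <speciesReference species="S1" stoichiometry="1"/>
          <speciesReference species="S2" stoichiometry="2"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="P" stoichiometry="1"/>
        </listOfProducts>
        <listOfModifiers>
          <modifierSpeciesReference species="E" sboTerm="SBO:0000013"/>
        </listOfModifiers>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


class TestConvert:
    def test_glyph_and_arc_counts(self):
        m = convert(SIMPLE)
        assert m.language is Language.PD
        by_cls = {}
        for g in m.glyphs:
            by_cls.setdefault(g.cls, []).append(g)
        assert len(by_cls["process"]) == 1
        assert len(by_cls["compartment"]) == 1
        # 4 species usages as shared glyphs
        entities = [g for g in m.glyphs
                    if g.cls not in ("process", "compartment")]
        assert len(entities) == 4
        arcs = {}
        for a in m.arcs:
            arcs.setdefault(a.cls, []).append(a)
        assert len(arcs["consumption"]) == 2
        assert len(arcs["production"]) == 1
        assert len(arcs["catalysis"]) == 1

    def test_sbo_terms_drive_classes(self):
        m = convert(SIMPLE)
        index = {g.id: g for g in m.glyphs}
        assert index["S1"].cls == "simple chemical"
        assert index["S2"].cls == "macromolecule"  # default

    def test_stoichiometry_becomes_cardinality(self):
        m = convert(SIMPLE)
        card = {a.source: a.cardinality for a in m.arcs
                if a.cls == "consumption"}
        assert card == {"S1": None, "S2": 2}

    def test_species_only_model(self):
        xml = SIMPLE.split(b"<listOfReactions>")[0] + b"</model></sbml>"
        m = convert(xml)
        assert all(g.cls != "process" for g in m.glyphs)
        assert m.arcs == []
        entities = [g for g in m.glyphs if g.cls != "compartment"]
        assert len(entities) == 4

    def test_unsupported_level_rejected(self):
        bad = SIMPLE.replace(b'level="3"', b'level="1"')
        with pytest.raises(SbgnFormatError, match="level"):
            convert(bad)

    def test_missing_species_reference_rejected(self):
        bad = SIMPLE.replace(b'species="P" stoichiometry="1"',
                             b'species="GHOST" stoichiometry="1"')
        with pytest.raises(UnresolvedReferenceError, match="GHOST"):
            convert(bad)

    def test_clone_threshold_duplicates_cofactors(self):
        # S1 participates in both reactions
        xml = SIMPLE.replace(
            b"</listOfReactions>",
            b'<reaction id="R2" reversible="false">'
            b'<listOfReactants><speciesReference species="S1" '
            b'stoichiometry="1"/></listOfReactants>'
            b'<listOfProducts><speciesReference species="S2" '
            b'stoichiometry="1"/></listOfProducts>'
            b"</reaction></listOfReactions>")
        m = convert(xml, ConversionRules(clone_threshold=1))
        s1 = [g for g in m.glyphs if g.id.startswith("S1")]
        assert len(s1) == 2 and all(g.clone for g in s1)

    def test_reversibility_recorded_as_unit_of_information(self):
        xml = SIMPLE.replace(b'reversible="false"', b'reversible="true"')
        m = convert(xml)
        proc = next(g for g in m.glyphs if g.cls == "process")
        assert [c.cls for c in proc.children] == ["unit of information"]
        assert proc.children[0].label == "reversible"

    def test_random_model_counting_oracle(self):
        """process glyphs == reactions; consumption arcs == reactant refs;
        modifier arcs == modifier refs; zero catalog violations."""
        for seed in range(50):
            xml = generate_random_sbml(seed)
            model = read_sbml(xml)
            m = convert(xml)
            procs = [g for g in m.iter_glyphs() if g.cls == "process"]
            assert len(procs) == len(model.reactions), seed
            n_reactants = sum(len(r.reactants) for r in model.reactions)
            n_mods = sum(len(r.modifiers) for r in model.reactions)
            assert sum(a.cls == "consumption" for a in m.arcs) == n_reactants
            assert sum(a.cls not in ("consumption", "production")
                       for a in m.arcs) == n_mods
            errors = [v for v in validate_map(m) if v.severity == "error"]
            assert errors == [], (seed, errors[:3])

    def test_species_and_reaction_ids_conserved(self):
        for seed in range(10):
            model = read_sbml(generate_random_sbml(seed))
            m = convert(generate_random_sbml(seed))
            glyph_ids = {g.id for g in m.iter_glyphs()}
            labels = {g.label for g in m.iter_glyphs()}
            for sid, *_ in model.species:
                assert sid in labels or \
                    any(gid == sid or gid.startswith(f"{sid}.")
                        for gid in glyph_ids)
            for r in model.reactions:
                assert sum(1 for g in m.iter_glyphs()
                           if g.cls == "process" and g.label == r.id) == 1


class TestAutoLayout:
    def test_reactant_process_product_ordering(self):
        laid = auto_layout(convert(SIMPLE))
        index = {g.id: g for g in laid.glyphs}
        proc = next(g for g in laid.glyphs if g.cls == "process")
        assert index["S1"].bbox.center[0] < proc.bbox.center[0]
        assert proc.bbox.center[0] < index["P"].bbox.center[0]

    def test_every_glyph_positive_extent(self):
        laid = auto_layout(convert(SIMPLE))
        for g in laid.iter_glyphs():
            assert g.bbox.w > 0 and g.bbox.h > 0, g.id

    def test_two_reactions_distinct_process_boxes(self):
        xml = SIMPLE.replace(
            b"</listOfReactions>",
            b'<reaction id="R2" reversible="false">'
            b'<listOfReactants><speciesReference species="P" '
            b'stoichiometry="1"/></listOfReactants>'
            b'<listOfProducts><speciesReference species="S1" '
            b'stoichiometry="1"/></listOfProducts>'
            b"</reaction></listOfReactions>")
        laid = auto_layout(convert(xml))
        procs = [g for g in laid.glyphs if g.cls == "process"]
        assert len(procs) == 2
        assert not procs[0].bbox.intersects(procs[1].bbox)

    def test_no_overlaps_over_50_random_models(self):
        """pairwise bbox intersection oracle: non-compartment glyphs are
        mutually disjoint, and compartments are disjoint from each other."""
        for seed in range(50):
            laid = auto_layout(convert(generate_random_sbml(seed)))
            tops = [g for g in laid.glyphs if g.cls != "compartment"]
            comps = [g for g in laid.glyphs if g.cls == "compartment"]
            for group in (tops, comps):
                for i in range(len(group)):
                    for j in range(i + 1, len(group)):
                        assert not group[i].bbox.intersects(group[j].bbox), \
                            (seed, group[i].id, group[j].id)

    def test_members_inside_their_compartment(self):
        laid = auto_layout(convert(SIMPLE))
        comp = next(g for g in laid.glyphs if g.cls == "compartment")
        for g in laid.glyphs:
            if g.compartment_ref == comp.id:
                assert comp.bbox.x <= g.bbox.x
                assert g.bbox.x + g.bbox.w <= comp.bbox.x + comp.bbox.w

    def test_deterministic_bytes(self):
        from sbgngraph import write_map
        from sbgngraph.sbgnml_io import SbgnDocument
        import io
        outs = []
        for _ in range(2):
            laid = auto_layout(convert(generate_random_sbml(7)))
            buf = io.BytesIO()
            write_map(SbgnDocument(map=laid), buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_input_map_not_mutated(self):
        m = convert(SIMPLE)
        before = [(g.id, g.bbox) for g in m.iter_glyphs()]
        auto_layout(m)
        assert [(g.id, g.bbox) for g in m.iter_glyphs()] == before
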