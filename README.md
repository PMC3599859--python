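# sbgngraph

SBGN diagrams as analysis graphs.

The Systems Biology Graphical Notation (SBGN) is the community standard
for drawing biological networks, split into three complementary
languages: **Process Description** (PD, biochemical reactions and state
transitions), **Entity Relationship** (ER, influences between entities)
and **Activity Flow** (AF, activation/inhibition between activities).
Maps are stored as SBGN-ML (XML). Network-analysis tooling, however,
expects plain attribute graphs — and several SBGN arc classes, container
glyphs and clone-marked duplicates do not fit that shape directly.

`sbgngraph` is a library + CLI for people who want to *compute* on SBGN
maps, not just look at them:

* **SBGN-ML I/O** — read and write all three languages, exposing every
  stored attribute (classes, labels, bounding boxes, ports, clone
  markers, cardinalities); unknown XML elements are preserved verbatim,
  and edited layouts (new node positions) can be exported back.
* **Property-graph conversion** — a `networkx.MultiDiGraph` with one
  attributed node per glyph and one edge per arc. The three composite
  arc classes with double terminal decorations — *necessary
  stimulation*, *absolute stimulation*, *absolute inhibition* — have no
  single simple-edge equivalent; they are decomposed into two sub-edges
  joined by an invisible auxiliary node at the arc midpoint (necessary
  stimulation = inhibition followed by stimulation; the absolute classes
  double their base mark). Both sub-edges keep the original arc id and
  class, so the step is exactly invertible.
* **Simplification** — a copy of the graph fit for topology analysis:
  decomposed pairs collapsed back to single edges (the edge *type*
  attribute is preserved; only the shape changed), compartments / tags /
  submaps dropped, and clone-marked entity pools (ATP, ADP, ...) merged
  into one node per (class, label).
* **SBML → SBGN** — generate a PD map from an SBML Level 2/3 model
  (species/reactions/modifiers → glyphs/arcs, SBO terms choosing glyph
  and arc classes) with a deterministic layered layout.
* **SVG rendering** — native SBGN shapes and arc terminals, with an
  `sbgn` profile (white terminal fill) and a `cytoscape` profile (black
  fill), deterministic z-order (compartments backmost, transparent), and
  a side-by-side HTML comparison matrix against other tools' renders.
* **Analysis** — minimum-hop shortest paths between named entities and
  labeled-motif matching (subgraph monomorphism, patterns ≤ 6 nodes),
  run on the simplified graph by default so auxiliary nodes never skew
  the topology.
* **Fixture suite** — a deterministic generator of minimal SBGN-ML test
  maps covering every glyph and arc class of all three reference cards,
  plus a toy metabolic chain with clone-marked cofactors.

## Worked example

Generate a 3-reaction toy chain (pyruvate → M1 → M2 → succinate, each
reaction consuming a clone-marked ATP and producing a clone-marked ADP),
then ask for the metabolic route:

```sh
$ sbgngraph toy --reactions 3 --clones --seed 1 --out toy.sbgn
$ sbgngraph path toy.sbgn --from pyruvate --to succinate --directed
m0 -> p1 -> m1 -> p2 -> m2 -> p3 -> m3
6 hops
```

The 7-node, 6-hop path alternates the 4 metabolites with the 3 process
nodes. It is computed on the *simplified* graph, so the six ATP/ADP
clone glyphs (merged to one pooled node each) neither appear in the path
nor distort it.

```sh
$ sbgngraph simplify toy.sbgn --nodes nodes.tsv --edges edges.tsv --report report.json
$ python -m json.tool report.json
{
    "removed": {},
    "clone_groups": [
        {"survivor": "adp1", "absorbed": ["adp2", "adp3"]},
        {"survivor": "atp1", "absorbed": ["atp2", "atp3"]}
    ],
    "collapsed_arcs": []
}
```

The TSV tables are plain attribute tables (one row per node/edge,
columns = union of attribute keys) ready for import into Cytoscape or
pandas. Other commands: `validate`, `roundtrip`, `tograph`, `render`,
`compare`, `fixtures`, `sbml2sbgn`, `motif` — see `sbgngraph --help`.

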