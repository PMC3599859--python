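# Methods

This note records the models, conventions and numerical choices behind
`sbgngraph`, and what the synthetic test data does and does not show.

## Map model and catalog

A map is a language tag (PD / ER / AF) plus glyphs and arcs. Glyphs
carry id, class token, optional label, a top-left + extent bounding box
(map units), optional `compartmentRef`, ports, nested sub-glyphs, a
clone flag and an optional orientation. Arcs carry class, source/target
(glyph or port id), start/end points, ordered bend points and an
optional integer cardinality (≥ 1).

Class tokens are the lower-case, space-separated strings of SBGN-ML
itself ("necessary stimulation", "macromolecule multimer", ...), and the
per-language catalogs of legal tokens are shipped as data
(`data/catalog.json`), following the SBGN reference cards of the
milestone-0.2 era. Multimer variants are distinct tokens, mirroring the
file format. Validation is structural only: id uniqueness, reference
resolution, class-in-language, compartment references naming
compartments. Nesting legality is checked one level deep; deeper
nesting is reported as a warning, not an error — rule-based semantic
validation is deliberately out of scope.

## SBGN-ML I/O

The writer targets the `http://sbgn.org/libsbgn/0.2` namespace; the
reader accepts any `sbgn.org` namespace and records the one it saw.
Coordinates are kept exactly as stored (top-left + extent); centers are
a computed view, so no lossy conversion happens on read. Numbers are
written in shortest round-trip decimal form, which makes
read → write → read semantically loss-free (geometry compared at 1e-9)
and write deterministic to the byte. Elements the reader does not model
are kept as raw fragments in a per-document ledger and re-emitted on
write. Writing refuses maps with unresolved references and reports the
offending ids. Layout export (`apply_layout`) translates each named
glyph (with its ports and sub-glyphs) so its center matches the
requested point, and translates arc endpoints by the delta of the glyph
they attach to; bend points are left where they are. Full documents are
exported, not deltas.

## Decomposition into property graphs

The conversion produces a `networkx.MultiDiGraph`. Every glyph that is
not an auxiliary *unit* becomes a node (compartments, tags, submaps and
logic operators included); state variables and units of information
become attributes of their parent node (`state_variables`,
`units_of_information`, semicolon-joined). Complex members and submap
terminals become nodes linked to their parent by a containment edge of
class `"part of"` — a package convention, chosen so that membership
survives into the tabular exports. Edge direction always follows the
arc's stored source → target; consumption arcs therefore point entity →
process as in the file.

Decomposition recipes:

| arc class             | first segment | second segment |
|-----------------------|---------------|----------------|
| necessary stimulation | inhibition    | stimulation    |
| absolute stimulation  | stimulation   | stimulation    |
| absolute inhibition   | inhibition    | inhibition     |

The necessary-stimulation split follows the standard reading of its
combined bar+arrow terminal; the two absolute classes double their base
mark, matching their doubled terminal decorations. The recipe table is
configurable. The auxiliary node sits at the arc's geometric midpoint
(middle bend point when bends exist), has near-zero extent (0.1 units)
and is flagged `is_auxiliary`. Ids are derived for reversibility:
auxiliary node `<arc>.aux`, sub-edges `<arc>.1` / `<arc>.2`, both
sub-edges carrying `original_arc` and `original_class`. This makes the
count identity exact — decomposition adds exactly one node and one edge
per composite arc — and the collapse an exact inverse (verified by
attribute-respecting isomorphism in the tests).

## Simplification

`simplify` returns a new graph (copy-on-write; the input is asserted
bit-identical before/after in the tests) in three passes: collapse
auxiliary triples back to single edges carrying the original class;
remove compartment/tag/submap/terminal nodes with their incident edges
(terminals are reported under the submap category); merge clones.
An auxiliary node without exactly one in- and one out-edge is a
structural error, never silently patched.

Clone handling **merges** rather than deletes: deleting clone-marked
pools (ATP, ADP, NADH...) would disconnect every reaction they touch,
defeating the purpose of cleaning the topology. The merge key is
(class, label); unlabeled clones are never merged because SBGN-ML
offers no safer identity. The lexicographically smallest id survives;
rewired parallel edges that become identical in (source, target, class)
are deduplicated, but pre-existing parallel edges elsewhere are left
alone. The `compartment` attribute on member nodes is retained as text
after compartment removal, so no information is lost. Simplification is
idempotent.

Merging clones changes reachability by design: on the toy chain the
pooled ADP node creates an undirected shortcut between all processes.
Path queries on metabolic maps should therefore use directed mode,
which follows reaction flow and is immune to pooled-cofactor
shortcuts; both modes are exposed.

## SBML → SBGN conversion

Species map to entity-pool glyphs (SBO 247/299 → simple chemical,
245/252 → macromolecule, 250/251 → nucleic acid feature, 253 → complex,
285 → unspecified entity; default macromolecule). Each reaction becomes
one process glyph; reactants/products become consumption/production
arcs (stoichiometry > 1 → arc cardinality); modifiers map by SBO term
(13/460/461 → catalysis, 20/206/207 → inhibition, 21/459 → stimulation,
default modulation). Reversible reactions stay one process with a
"reversible" unit-of-information decoration, since PD has no
reversible-process glyph. The display label prefers the SBML `name`
and falls back to the id; glyph ids embed the SBML ids, so provenance
is always recoverable. By default each species is one shared glyph;
`clone_threshold=k` duplicates species used in more than *k* reactions
as clone-marked per-usage glyphs (the usual SBGN treatment of
cofactors). The SBO tables are data with stated defaults, not code.

The layered layout places reactants / processes+modifiers / products in
three columns (gaps 120 × 80 units, glyphs 80 × 40, processes 30 × 30),
stacking reactions vertically. Glyphs are grouped into one vertical
band per compartment, and each glyph occupies its own grid cell, so all
non-compartment glyphs are pairwise disjoint and compartment boxes —
drawn as enclosing rectangles around their members with half-margin
padding — are disjoint from each other. A container overlapping its own
members is containment, not a collision, so the no-overlap guarantee is
stated for non-compartment pairs and compartment–compartment pairs.
The layout is purely deterministic; converting and laying out the same
model twice yields byte-identical SBGN-ML.

## Rendering

Shapes are emitted as native SVG primitives per the reference cards; no
raster images. Compartments are drawn first (largest first) with
transparent fill, so stacking is deterministic back-to-front and
enclosed nodes stay visible; each glyph and arc gets an id-tagged
`<g>` group, with sub-glyph groups nested after the parent's own shape.
Arc terminals are drawn as explicit rotated paths rather than SVG
markers so the fill is controllable: the `sbgn` profile fills open
decorations white, the `cytoscape` profile black; production arrowheads
are solid in both. The renderer always draws the *original* arc class —
decomposition is an analysis concern, not a visual one. Rendering a map
with non-positive glyph extents is an error listing the offending ids.
Selection-state styling is out of scope (SVG has no selection state).

The comparison page is a plain HTML table, one row per case, columns =
reference, external tools, this package's fresh render; missing images
become marked cells, never dropped rows.

## Synthetic data

The fixture suite derives one minimal case per catalog glyph class and
arc class per language, plus three composite cases each (compartment
containment, complex/submap nesting, a clone pair): 39 PD + 36 ER +
21 AF = 96 cases. The public libSBGN render-comparison suite has
8 AF / 18 ER / 27 PD files; our counts are catalog-derived rather than
forced to match, and the manifest records both. Fixture geometry is a
fixed grid — the suite exercises classes and structure, not layout
stress; arc endpoints are class-legal for the language but not
role-checked (role legality is semantic validation, a non-goal). The
toy metabolic chain (M0 "pyruvate" → p1 → ... → pn → Mn "succinate",
optional clone-marked ATP/ADP per reaction) is a desk-scale stand-in
for a genome-scale metabolic map: it reproduces the structural features
the simplifier and analyses depend on (clones, linear reaction
topology) but none of the scale, branching or annotation richness of
real maps, so passing tests demonstrate correctness of the operations,
not performance or robustness on curated pathway archives. Random SBML
models (2–8 species, 1–5 reactions, seeded) likewise probe the
conversion contracts, not biochemical realism.

## Analysis

Shortest paths are minimum-hop (edges are unweighted; SBGN arcs carry
no costs), computed by breadth-first distance labelling from the target
followed by greedy reconstruction, which yields the lexicographically
smallest id sequence among equal-length paths — a determinism choice,
not a semantic one. Endpoints may be ids or unique labels; ambiguous
labels raise with the candidate list. By default both analyses run on
the simplified graph, because auxiliary nodes would otherwise be
counted as path steps; `raw=True` analyses the graph as built.

Motif matching is subgraph monomorphism (non-induced; an `induced` flag
switches semantics) by backtracking over sorted candidates, with node
constraints (class token, tuple of tokens, or the `epn` meta-class) and
per-edge arc-class constraints. Patterns are capped at 6 nodes — the
matcher is exact and brute-force-verifiable at that size. Embeddings
equivalent under a pattern automorphism are reported once,
canonicalised by the minimal mapped tuple; output order is sorted.
Both analyses are checked against exhaustive enumeration on all
fixture graphs of ≤ 12 nodes.

## Limitations

* The catalog follows the milestone-0.2 reference cards; later SBGN
  milestone extensions (e.g. PD equivalence operators, render-extension
  styling) are not modelled, and CellDesigner SBML-extension files are
  not read.
* Clone merging by (class, label) can over-merge distinct pools that
  share a label across compartments; the compartment attribute is
  retained so downstream code can detect this, but the merge itself
  does not key on it.
* The layered layout is schematic (grid bands), not an aesthetic
  pathway layout; it guarantees disjointness and determinism only.
* Rendering aims at faithful class-distinguishable shapes, not
  pixel-parity with any other tool.
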