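{
  "_comment": "Per-language catalogs of legal SBGN-ML class tokens, following the SBGN reference cards (milestone-0.2 era tokens, lower-case, space-separated).",
  "process description": {
    "glyph": [
      "unspecified entity",
      "simple chemical",
      "macromolecule",
      "nucleic acid feature",
      "complex",
      "simple chemical multimer",
      "macromolecule multimer",
      "nucleic acid feature multimer",
      "complex multimer",
      "source and sink",
      "perturbing agent",
      "phenotype",
      "process",
      "omitted process",
      "uncertain process",
      "association",
      "dissociation",
      "compartment",
      "submap",
      "tag",
      "terminal",
      "and",
      "or",
      "not",
      "state variable",
      "unit of information",
      "cardinality"
    ],
    "arc": [
      "consumption",
      "production",
      "modulation",
      "stimulation",
      "catalysis",
      "inhibition",
      "necessary stimulation",
      "logic arc",
      "equivalence arc"
    ]
  },
  "entity relationship": {
    "glyph": [
      "unspecified entity",
      "simple chemical",
      "macromolecule",
      "nucleic acid feature",
      "perturbing agent",
      "phenotype",
      "interaction",
      "outcome",
      "existence",
      "location",
      "variable value",
      "implicit xor",
      "delay",
      "and",
      "or",
      "not",
      "state variable",
      "unit of information",
      "tag",
      "terminal",
      "submap",
      "annotation",
      "cardinality"
    ],
    "arc": [
      "interaction",
      "assignment",
      "modulation",
      "stimulation",
      "inhibition",
      "necessary stimulation",
      "absolute stimulation",
      "absolute inhibition",
      "logic arc",
      "equivalence arc"
    ]
  },
  "activity flow": {
    "glyph": [
      "biological activity",
      "phenotype",
      "perturbation",
      "and",
      "or",
      "not",
      "delay",
      "compartment",
      "submap",
      "tag",
      "terminal",
      "unit of information"
    ],
    "arc": [
      "positive influence",
      "negative influence",
      "unknown influence",
      "necessary stimulation",
      "logic arc",
      "equivalence arc"
    ]
  }
}
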