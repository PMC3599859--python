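"""Exception hierarchy shared across the package.

The CLI maps these onto its exit-code contract: usage problems exit 1,
input/format problems exit 2, validation failures exit 3.
"""


class SbgnError(Exception):
    """Base class for all package-specific errors."""


class SbgnFormatError(SbgnError):
    """Malformed or unsupported input document (SBGN-ML or SBML)."""


class CatalogError(SbgnError):
    """A (language, class) combination not present in the reference-card catalog."""


class UnresolvedReferenceError(SbgnError):
    """An id reference (glyph, port, species) does not resolve."""

    def __init__(self, message: str, ids=()):
        super().__init__(message)
        self.ids = list(ids)


class StructuralError(SbgnError):
    """A graph violates a structural precondition (e.g. auxiliary node degree != 2)."""


class AmbiguousLabelError(SbgnError):
    """A node label matched more than one node where a unique one was required."""

    def __init__(self, message: str, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)
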