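"""Exception hierarchy shared by all pathphylo modules."""


class PathPhyloError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PathPhyloError):
    """An input violates a documented precondition or invariant."""


class ParseError(PathPhyloError):
    """A document (KGML, Newick, TSV) could not be parsed."""


class MappingError(PathPhyloError):
    """A namespace map does not cover the identifiers it must map."""
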