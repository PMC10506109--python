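"""Exception hierarchy shared across orfkit modules."""


class OrfkitError(Exception):
    """Base class for all orfkit-specific errors."""


class ParseError(OrfkitError):
    """File-level syntax error (aborts the read)."""


class ValidationError(OrfkitError):
    """Domain invariant violated by an otherwise well-formed record."""


class MappingError(OrfkitError):
    """Coordinate mapping failure (e.g. ORF base outside transcript exons)."""
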