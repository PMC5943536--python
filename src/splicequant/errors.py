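"""Exception hierarchy shared across the pipeline.

Distinct classes map to distinct CLI exit codes, so a caller can tell a
malformed input apart from a violated model assumption.
"""


class SpliceQuantError(Exception):
    """Base class for all package errors."""


class AnnotationError(SpliceQuantError):
    """The exon annotation is unusable (overlapping exons, mixed strands, ...)."""


class ParseError(SpliceQuantError):
    """An input file does not conform to its declared format."""


class ConfigError(SpliceQuantError):
    """A run or simulation configuration is internally inconsistent."""


class NormalizationError(SpliceQuantError):
    """Reference-junction accounting failed (negative full-length, zero RJ)."""
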