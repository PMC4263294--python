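"""Exception hierarchy shared across the pipeline.

All data-level failures raise :class:`OxomapError` subclasses so the CLI can
translate them into a nonzero exit with a one-line cause.
"""


class OxomapError(Exception):
    """Base class for all pipeline errors."""


class ParseError(OxomapError):
    """A file could not be parsed; message carries path and line number."""


class ValidationError(OxomapError):
    """Inputs violate a documented precondition or invariant."""


class DegenerateStatisticError(OxomapError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
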