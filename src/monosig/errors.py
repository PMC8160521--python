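"""Exception hierarchy for monosig.

Every failure mode raised by the library derives from :class:`MonosigError`
so callers (and the CLI) can catch one base class.
"""


class MonosigError(Exception):
    """Base class for all monosig errors."""


class ParameterError(MonosigError, ValueError):
    """An argument or configuration field is invalid; the message names it."""


class SchemaError(MonosigError, ValueError):
    """A table is structurally inconsistent (missing samples, duplicates...)."""


class ParseError(MonosigError, ValueError):
    """A file could not be parsed; the message carries coordinates."""


class FormatError(MonosigError, ValueError):
    """A value cannot be serialized in the requested text format."""


class AlignmentError(MonosigError, ValueError):
    """Gene/feature indices of two objects do not line up."""


class InsufficientDataError(MonosigError, ValueError):
    """Too few samples/values to compute the requested statistic."""


class UndefinedEffectError(MonosigError, ArithmeticError):
    """An effect size is undefined (e.g. zero pooled standard deviation)."""


class CoverageError(MonosigError, ValueError):
    """Too few signature genes are measured in the dataset."""
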