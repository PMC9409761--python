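"""Exception hierarchy.

``PhenodivError`` is the base for every user-facing error; the CLI maps it
to exit code 1 and anything else to exit code 2.
"""


class PhenodivError(Exception):
    """Base class for all errors raised by phenodiv."""


class FormatError(PhenodivError):
    """An input file does not have the required columns or encoding."""


class LayoutError(PhenodivError):
    """A trial violates the augmented-RCBD layout invariants."""


class ValidationError(PhenodivError):
    """A value is outside its declared domain (e.g. unknown state code)."""


class ConfigError(PhenodivError):
    """A simulation or pipeline configuration is inconsistent."""


class AdjustmentError(PhenodivError):
    """Block effects cannot be estimated (missing check observation)."""


class DomainError(PhenodivError):
    """An operation was called outside its mathematical domain."""
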