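"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: ParseError -> 3, ValidationError -> 4,
ComputationError -> 5.  Anything else is a bug.
"""


class PhageKitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(PhageKitError):
    """A file could not be read as the named format."""


class ValidationError(PhageKitError):
    """Input violated a precondition (bad thresholds, empty data, ...)."""


class ComputationError(PhageKitError):
    """A computation could not produce a result (e.g. no burst detected)."""


class TooShortError(ValidationError):
    """Sequence has fewer standard residues than the minimum length."""
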