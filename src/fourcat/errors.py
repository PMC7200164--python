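"""Exception hierarchy shared across the toolkit.

``DataValidationError`` covers malformed or inconsistent inputs (exit code 3
in the CLI); ``NumericError`` covers mathematically degenerate situations such
as empty denominators or constant vectors (exit code 4).
"""


class FourcatError(Exception):
    """Base class for all toolkit errors."""


class DataValidationError(FourcatError):
    """Input data are malformed or inconsistent with the fragment map."""


class NumericError(FourcatError):
    """A computation is degenerate (zero denominator, constant input, ...)."""
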