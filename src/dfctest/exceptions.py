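"""Exception hierarchy.

``DfcUserError`` subclasses indicate problems with user-supplied data or
parameters (CLI exit code 1); anything else escaping the library is treated
as an internal error (CLI exit code 2).
"""


class DfcError(Exception):
    """Base class for all package errors."""


class DfcUserError(DfcError):
    """Errors attributable to user input (data, parameters, files)."""


class DataValidationError(DfcUserError):
    """Invalid dataset: shape, missing values, labels, duplicate IDs."""


class ParseError(DfcUserError):
    """Malformed input file; message names the offending line/column."""


class ParameterError(DfcUserError):
    """Parameter outside its documented range."""


class SizeError(DfcUserError):
    """Too few samples or features for the requested operation."""


class DegenerateVarianceError(DfcError):
    """All variance terms are zero where a positive variance is required."""


class DomainError(DfcError):
    """Argument outside the mathematical domain of the operation."""


class EstimationError(DfcError):
    """Null-model estimation failed (bin too sparse, degenerate scale...)."""
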