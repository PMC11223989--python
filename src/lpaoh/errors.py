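"""Exception hierarchy shared across the package.

Exit codes (used by the CLI): 0 ok, 2 input error, 3 insufficient data.
"""


class LpaohError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(LpaohError):
    """Malformed, unsorted, out-of-range or otherwise unusable input data."""

    exit_code = 2


class ParameterError(InputError):
    """A parameter value outside its documented range."""


class InsufficientDataError(LpaohError):
    """The input is well-formed but carries too little information to proceed."""

    exit_code = 3
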