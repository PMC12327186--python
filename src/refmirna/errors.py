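"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation errors -> 2, contract
errors -> 3, I/O errors -> 4.
"""


class RefMirnaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(RefMirnaError):
    """Input data violates a documented invariant (bad Ct value, duplicate id, ...)."""

    exit_code = 2


class ContractError(RefMirnaError):
    """An operation was called outside its preconditions (too few groups, ...)."""

    exit_code = 3


class InputOutputError(RefMirnaError):
    """A file could not be read, parsed or written."""

    exit_code = 4
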