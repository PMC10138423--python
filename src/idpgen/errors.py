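"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage errors are handled by
click itself): :class:`DataError` -> 3, :class:`NumericalError` -> 4.
"""


class IdpgenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IdpgenError):
    """Malformed or inconsistent input file (e.g. ragged multi-model PDB)."""


class DataError(IdpgenError):
    """Structurally valid input that violates an operation's preconditions."""


class NumericalError(IdpgenError):
    """Numerical failure at run time (NaN loss, singular matrix, ...)."""
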