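"""Exception hierarchy.

All library errors derive from :class:`ShiftwaveError` so callers can
catch one type; the leaf classes also derive from the matching builtin
(``ValueError`` for bad arguments, ``RuntimeError`` for structural
problems) to stay idiomatic.
"""


class ShiftwaveError(Exception):
    """Base class for all shiftwave errors."""


class InvalidArgumentError(ShiftwaveError, ValueError):
    """An argument is outside its documented domain."""


class UnsupportedOrderError(ShiftwaveError, ValueError):
    """Daubechies order outside the numerically supported range."""


class DivisibilityError(ShiftwaveError, ValueError):
    """Signal length not divisible by 2**levels."""


class IncompatibleFilterBankError(ShiftwaveError, ValueError):
    """A decomposition is paired with a differently named filter bank."""


class StructuralError(ShiftwaveError, RuntimeError):
    """Internally inconsistent container (ragged lengths etc.)."""


class DegenerateInputError(ShiftwaveError, ValueError):
    """Input is degenerate for the requested analysis (e.g. all zero)."""


class SignalFormatError(ShiftwaveError, ValueError):
    """A signal file does not follow the expected CSV layout."""
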