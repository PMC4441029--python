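"""Exception hierarchy for rhythmcat.

All errors derive from :class:`RhythmcatError` so callers can catch the
package's failures with a single except clause.
"""


class RhythmcatError(Exception):
    """Base class for all rhythmcat errors."""


class ConfigurationError(RhythmcatError, ValueError):
    """A configuration value is inconsistent or outside its admissible domain."""


class ValidationError(RhythmcatError, ValueError):
    """An input object violates a documented precondition or invariant."""


class NumericalDomainError(RhythmcatError, ArithmeticError):
    """A state or stimulus value left the domain where the model equations
    are defined (e.g. a coupling denominator within 1e-12 of zero)."""


class IntegrationError(NumericalDomainError):
    """The oscillator state escaped the sqrt(eps)*|z| < 1 domain during
    numerical integration; carries the offending oscillator and time."""

    def __init__(self, message: str, oscillator: int | None = None,
                 time: float | None = None):
        super().__init__(message)
        self.oscillator = oscillator
        self.time = time


class UndefinedSNRError(RhythmcatError, ValueError):
    """The signal-to-noise ratio of an all-zero activation pattern is
    undefined (distinct from the +inf of a perfectly concentrated pattern)."""


class UndefinedCorrelationError(RhythmcatError, ValueError):
    """Pearson correlation is undefined (zero variance in one variable)."""
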