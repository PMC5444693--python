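"""Exception hierarchy.

Every error raised by the package derives from :class:`PathdynError`, so
callers (and the CLI) can catch one type at the boundary.
"""


class PathdynError(Exception):
    """Base class for all pathdyn errors."""


class SBMLFormatError(PathdynError):
    """The file is not parseable SBML of a supported level/version."""


class UnsupportedFeatureError(PathdynError):
    """A valid SBML construct outside the supported core subset.

    The message names the offending construct (e.g. ``listOfEvents``,
    ``piecewise``).
    """


class IntegrityError(PathdynError):
    """Referential integrity violated (undeclared species, unresolved symbol)."""


class ValidationError(PathdynError):
    """A value violates a domain invariant (negative dosage, bad range)."""


class UnknownTargetError(PathdynError, KeyError):
    """Lookup of a drug, species, or reaction id failed."""


class SimulationError(PathdynError):
    """The integrator failed; ``last_good_time`` holds the last reached time."""

    def __init__(self, message: str, last_good_time: float | None = None):
        super().__init__(message)
        self.last_good_time = last_good_time


class AlignmentError(PathdynError):
    """Two trajectories cannot be compared (grid or entity-set mismatch)."""
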