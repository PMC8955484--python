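"""Exception hierarchy.

Validation problems raise :class:`ConfigError` (a ``ValueError``), numerical
problems raise subclasses of :class:`NumericalError` (a ``RuntimeError``) so
callers -- the CLI in particular -- can map them to distinct exit codes.
"""


class ConfigError(ValueError):
    """A configuration file or parameter set failed validation."""


class NumericalError(RuntimeError):
    """Base class for run-time numerical failures."""


class SolverError(NumericalError):
    """The equilibrium root search failed to converge or found no root in (0, Htot]."""


class InstabilityError(NumericalError):
    """A time step would have driven a donor membrane pool negative.

    Indicates the time-step rule (deplete at most a fixed fraction of a donor
    pool per step) was violated; the message names the offending pool and the
    last valid simulated time.
    """


class BracketError(NumericalError):
    """A dose search did not bracket the requested release level.

    Carries the achieved extrema so the caller can widen the search range.
    """

    def __init__(self, message: str, extrema: tuple[float, float] | None = None):
        super().__init__(message)
        self.extrema = extrema
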