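"""Exception hierarchy.

Every error raised by the library derives from :class:`MicrosurvError` so that
callers (and the CLI) can map failure classes onto exit codes.
"""


class MicrosurvError(Exception):
    """Base class for all library errors."""


class ParameterError(MicrosurvError, ValueError):
    """A model parameter violates its invariants (e.g. zF <= 0)."""


class DomainError(MicrosurvError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DataError(MicrosurvError, ValueError):
    """Malformed or insufficient input data (parse errors carry locations)."""


class GridError(MicrosurvError, ValueError):
    """Incompatible spectrum grids."""


class DegenerateSpectrumError(MicrosurvError, ValueError):
    """An all-zero or otherwise unnormalisable spectrum."""


class CoverageError(MicrosurvError, ValueError):
    """A fluence spectrum falls outside the tabulated energy/radius range."""


class ConfigurationError(MicrosurvError, ValueError):
    """Missing or inconsistent configuration (e.g. spectrum without geometry)."""


class ConditioningError(MicrosurvError, ValueError):
    """A regression design is rank-deficient or underdetermined."""


class ConvergenceError(MicrosurvError, RuntimeError):
    """An iterative solve failed to converge or found no bracket."""


class ModelValidityError(MicrosurvError, ValueError):
    """A regression model was evaluated outside its range of validity."""
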