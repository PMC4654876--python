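"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4.
"""


class BovigenError(Exception):
    """Base class for all package errors."""


class ConfigError(BovigenError):
    """A configuration value violates an invariant."""


class DataError(BovigenError):
    """Input data is malformed or inconsistent (alignment, missingness, cycles)."""


class ConvergenceError(BovigenError):
    """An iterative fit failed to converge; carries the last estimates."""

    def __init__(self, message, last_estimates=None):
        super().__init__(message)
        self.last_estimates = last_estimates


class IdentifiabilityWarning(UserWarning):
    """Variance components are not separately identifiable from the data."""
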