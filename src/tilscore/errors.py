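"""Exception hierarchy used across the pipeline.

Configuration, data and convergence failures are distinguished so the CLI
can map them onto distinct exit codes.
"""


class TilscoreError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TilscoreError):
    """A config object or parameter set is invalid (bad correlation matrix,
    missing cutoff, prevalence outside [0, 1], ...)."""


class DataError(TilscoreError):
    """Input data violate a precondition (empty group, zero events,
    mismatched lengths, negative density, ...)."""


class ConvergenceError(TilscoreError):
    """An iterative fit failed to converge or the likelihood is degenerate
    (e.g. perfect separation in a Cox model)."""
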