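"""Exception hierarchy.

The CLI maps these onto process exit codes: configuration problems exit 2,
data problems exit 3, and a model that did not converge exits 4.
"""


class TemporegError(Exception):
    """Base class for all package errors."""


class ConfigError(TemporegError):
    """Invalid configuration value (bad probability, empty window, ...)."""

    exit_code = 2


class DataError(TemporegError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class CodePatternError(ConfigError):
    """A diagnosis-code pattern does not parse under the supported grammar."""


class InsufficientVisitsError(DataError):
    """Fewer than three distinct qualifying visit dates."""


class DegenerateDistributionError(DataError):
    """A statistic is undefined on the given values (e.g. zero variance)."""


class CollinearityError(DataError):
    """Rank-deficient design matrix; carries the offending term names."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(f"collinear design terms: {', '.join(self.terms)}")


class ConvergenceWarning(UserWarning):
    """Model fitting stopped without meeting the convergence criterion."""
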