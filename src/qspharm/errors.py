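"""Exception hierarchy shared across the package.

Exit codes follow the CLI contract: 2 for configuration/validation problems,
3 for analysis/domain errors, 4 for I/O problems.
"""


class QSPharmError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(QSPharmError):
    """Invalid configuration: unknown dialect, bad parameter, missing profile."""

    exit_code = 2


class ValidationError(QSPharmError):
    """Malformed or out-of-contract input data."""

    exit_code = 2


class AnalysisError(QSPharmError):
    """Domain error raised during an analysis step (undefined quantity etc.)."""

    exit_code = 3


class TrainingError(AnalysisError):
    """Model training diverged or was misconfigured."""


class EvaluationError(AnalysisError):
    """Evaluation requested on an empty or inconsistent held-out set."""


class InputOutputError(QSPharmError):
    """File missing or unreadable."""

    exit_code = 4
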