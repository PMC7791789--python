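"""Exception hierarchy.

Each failure mode of the pipeline has a dedicated type so the CLI can map
errors to exit codes (config -> 2, data -> 3, numerical -> 4) and so tests
can assert on the precise contract that was violated.
"""


class CalensError(Exception):
    """Base class for all package errors."""


class ConfigError(CalensError):
    """Invalid configuration or invalid argument to an operation."""


class DataError(CalensError):
    """Malformed input data: parse failures, schema violations, unseen levels."""


class SchemaError(DataError):
    """A covariate value is not a declared level of its covariate."""


class DegenerateTrainingError(CalensError):
    """Training data contains a single outcome class."""


class StratificationError(CalensError):
    """A stratified split would leave a class without samples."""


class CalibrationFailure(CalensError):
    """A calibrator failed to fit (solver failure, infeasible grid, divergence)."""

    def __init__(self, message: str, status: object = None):
        super().__init__(message)
        self.status = status


class UndefinedMetricError(CalensError):
    """A metric is undefined on the given input (e.g. AUC with one class)."""


class NotFittedError(CalensError):
    """Predict called on an unfitted model or calibrator."""
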