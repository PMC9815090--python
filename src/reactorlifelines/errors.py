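"""Exception hierarchy for the lifeline pipeline.

Validation failures (bad configs, malformed files) are distinguished from
runtime/numerical failures (non-convergence, instability) so that the CLI can
map them to different exit codes.
"""


class ReactorLifelinesError(Exception):
    """Base class for all package errors."""


class ValidationError(ReactorLifelinesError):
    """Invalid user input: configuration, arguments, or file contents."""


class InvalidConfigurationError(ValidationError):
    """A network / kinetics / pipeline configuration violates its invariants."""


class SchemaValidationError(ValidationError):
    """A lifeline CSV (or sidecar) violates the documented schema."""


class RuntimeFailure(ReactorLifelinesError):
    """Numerical or algorithmic failure during a computation."""


class StabilityError(RuntimeFailure):
    """Explicit time step too large for the fastest compartment turnover."""


class NotConvergedError(RuntimeFailure):
    """An iteration (tracer curve, steady state, fixed point) did not converge."""


class CalibrationError(RuntimeFailure):
    """Network calibration failed; carries the best metrics achieved."""

    def __init__(self, message, best_metrics=None):
        super().__init__(message)
        self.best_metrics = best_metrics


class WashoutError(RuntimeFailure):
    """Substrate feed exceeds the maximum possible consumption: no steady state."""


class AbsorbingSubsetError(RuntimeFailure):
    """Residence-time query on a compartment subset with no exit flow."""


class EmptyLifelineError(ValidationError):
    """An operation would leave a lifeline with no samples."""
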