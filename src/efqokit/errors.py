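"""Exception hierarchy for the EFQO analysis pipeline."""


class EfqoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EfqoError, ValueError):
    """A delimited input file does not match the documented schema."""


class TraceValidationError(EfqoError, ValueError):
    """A kinetic trace or layout violates a structural invariant."""


class CalibrationError(EfqoError, ValueError):
    """The fluorescence calibration is missing, invalid, or ill-posed."""


class FitError(EfqoError, RuntimeError):
    """A nonlinear fit failed to converge or the model is unidentifiable."""


class PipelineError(EfqoError, RuntimeError):
    """A pipeline stage failed; carries the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
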