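"""Exception hierarchy with machine-readable codes for the pipeline stages."""


class UromirError(Exception):
    """Base class; ``code`` is a stable machine-readable identifier."""

    code = "error"
    exit_code = 1


class ConfigurationError(UromirError):
    code = "configuration_error"
    exit_code = 2


class MatchingError(UromirError):
    code = "matching_error"
    exit_code = 3


class SelectionError(UromirError):
    """Raised when internal-control selection cannot proceed."""

    code = "selection_error"
    exit_code = 4


class SplitError(UromirError):
    code = "split_error"
    exit_code = 5


class EvaluationError(UromirError):
    code = "evaluation_error"
    exit_code = 6


class StageError(UromirError):
    """Wraps any stage failure with the stage name for pipeline reporting."""

    code = "stage_error"
    exit_code = 7

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        cause_code = getattr(cause, "code", "error")
        self.code = f"{stage}:{cause_code}"
        super().__init__(f"stage '{stage}' failed ({cause_code}): {cause}")
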