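"""Exception hierarchy shared across tmakit modules."""


class TmakitError(Exception):
    """Base class for all package errors."""


class ParameterError(TmakitError, ValueError):
    """A configuration or argument value violates its contract."""


class EstimationError(TmakitError, RuntimeError):
    """An estimator cannot be evaluated on the given data."""


class DegenerateDataError(TmakitError, ValueError):
    """Input data carry no information for the requested statistic."""


class PipelineError(TmakitError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
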