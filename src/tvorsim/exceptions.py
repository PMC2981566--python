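"""Exception types shared across the package."""


class InsufficientDataError(ValueError):
    """Raised when there are too few unmasked samples to support a fit."""


class ParseError(ValueError):
    """Raised when a trial file or manifest does not conform to the schema."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
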