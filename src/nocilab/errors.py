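"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Raised when an input object or parameter violates its contract."""


class DegenerateSkeletonError(RuntimeError):
    """Raised when a skeleton lacks the two endpoints needed for a tip-to-tip length."""


class DiscardedTraceError(RuntimeError):
    """Raised when an operation is asked to analyze a trace that was discarded."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name and input id."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage
        self.detail = detail
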