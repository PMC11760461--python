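"""Exception types shared across the pipeline."""


class AngiovisError(Exception):
    """Base class for all package errors."""


class ParameterError(AngiovisError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class InputError(AngiovisError, ValueError):
    """An input image or array violates a precondition."""


class DegenerateInputError(AngiovisError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant values)."""


class PipelineError(AngiovisError, RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
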