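"""Exception hierarchy shared across the pipeline stages."""


class VakError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VakError):
    """An input table is missing mandatory columns or is structurally malformed."""


class ValidationError(VakError):
    """A value violates a domain invariant (e.g. KPS not a multiple of 10)."""


class ClassificationError(VakError):
    """A patient cannot be VAK-classified (missing size, age or KPS)."""


class ConvergenceError(VakError):
    """An iterative fit failed to converge (e.g. monotone Cox partial likelihood)."""


class StageError(VakError):
    """A pipeline stage aborted; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
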