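"""Exception hierarchy shared across the pipeline stages."""


class PhqScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(PhqScreenError, ValueError):
    """Input data violates a documented contract (bad file, bad label, bad shape)."""


class ConfigurationError(PhqScreenError, ValueError):
    """Unknown embedder, mismatched dimensions, or inconsistent configuration."""


class StageError(PhqScreenError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
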