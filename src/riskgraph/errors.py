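"""Exception types shared across the package."""


class RiskGraphError(Exception):
    """Base class for package-specific errors."""


class SchemaError(RiskGraphError, ValueError):
    """A required column or field is missing or malformed."""


class VocabularyError(RiskGraphError, ValueError):
    """A label falls outside its controlled vocabulary."""


class ConfigurationError(RiskGraphError, ValueError):
    """A parameter block violates its invariants."""


class PipelineError(RiskGraphError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
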