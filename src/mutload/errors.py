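"""Exception hierarchy shared across the package."""


class MutloadError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MutloadError):
    """Invalid configuration or input-validation failure."""


class SimulationError(MutloadError):
    """Forward simulation failed (e.g. population extinction)."""

    def __init__(self, message: str, generation: int | None = None):
        super().__init__(message)
        self.generation = generation


class VariantIOError(MutloadError):
    """Problem reading or writing genotype data."""


class ClassificationError(MutloadError):
    """Malformed or inconsistent annotation tables."""


class PipelineError(MutloadError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
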