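"""Exception hierarchy shared across the pipeline."""


class ULMError(Exception):
    """Base class for all ulmkit errors."""


class DomainError(ULMError, ValueError):
    """An input violates a physical or mathematical precondition."""


class EstimationError(ULMError, RuntimeError):
    """A measurement (FWHM, resolution, ...) cannot be formed from the data."""


class GenerationError(ULMError, RuntimeError):
    """Synthetic geometry could not be placed inside the field of view."""


class FitError(ULMError, RuntimeError):
    """A model fit failed to converge."""


class ConfigError(ULMError, ValueError):
    """Invalid or inconsistent pipeline configuration."""


class StageError(ULMError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
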