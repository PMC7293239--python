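"""Exception types shared across the package."""


class ChipcallError(Exception):
    """Base class for package errors."""


class FormatError(ChipcallError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ChipcallError):
    """A value violates a domain invariant."""


class ConfigurationError(ChipcallError):
    """Inconsistent run configuration (missing contexts, bad thresholds...)."""


class StageError(ChipcallError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
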