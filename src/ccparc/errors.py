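"""Exception hierarchy shared across the package."""


class CcparcError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CcparcError):
    """A file could not be parsed as the expected on-disk format."""


class ValidationError(CcparcError):
    """Parsed content violates a documented invariant."""


class PipelineError(CcparcError):
    """A processing stage could not produce a valid result."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
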