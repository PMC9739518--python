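"""Exception hierarchy shared across the package."""


class OdorBalanceError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(OdorBalanceError, ValueError):
    """A table file is malformed (bad header, duplicate ids, wrong shape)."""


class ValidationError(OdorBalanceError, ValueError):
    """A table parsed but violates a domain invariant (e.g. negative value)."""


class InsufficientDataError(OdorBalanceError, ValueError):
    """Too few observations to perform the requested computation."""


class EmptyResultError(OdorBalanceError, ValueError):
    """A filtering step would leave nothing to work with."""


class PipelineStageError(OdorBalanceError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
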