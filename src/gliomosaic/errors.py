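"""Exception hierarchy shared across the pipeline stages."""


class GliomosaicError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GliomosaicError):
    """Invalid simulation or stage configuration."""


class FormatError(GliomosaicError):
    """Malformed input file (dimension mismatch, duplicate ids, overlapping segments)."""


class EmptyAfterQCError(GliomosaicError):
    """Every cell was removed by quality filtering."""


class InvariantError(GliomosaicError):
    """A contract required by a downstream stage is violated (e.g. zero-total cell)."""


class StageError(GliomosaicError):
    """Pipeline stage failure carrying a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
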