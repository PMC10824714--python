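"""Exception hierarchy used across the toolkit."""


class HolopolError(Exception):
    """Base class for all toolkit errors."""


class ShapeError(HolopolError, ValueError):
    """Array shapes are inconsistent or not permitted (e.g. odd mosaic)."""


class ConfigError(HolopolError, ValueError):
    """Invalid or unknown configuration value."""


class GeometryError(HolopolError, ValueError):
    """A particle or channel geometry is degenerate or does not fit."""


class SamplingError(HolopolError, ValueError):
    """The requested render would alias on the detector grid."""


class EmptyRegionError(HolopolError, ValueError):
    """An operation requiring a non-empty pixel region received none."""


class InsufficientDataError(HolopolError, ValueError):
    """Fewer observations than the statistic requires."""


class FormatError(HolopolError, ValueError):
    """A file could not be parsed in the expected format."""


class StageError(HolopolError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
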