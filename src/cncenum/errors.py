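"""Exception hierarchy shared across the package."""


class CncEnumError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CncEnumError, ValueError):
    """Invalid layout, population-model, or run configuration."""


class GeometryError(CncEnumError, ValueError):
    """Image dimensions inconsistent with the chip layout."""


class PlacementError(CncEnumError, ValueError):
    """A cell lies outside the renderable image bounds."""


class InputError(CncEnumError, ValueError):
    """Required input (e.g. an image channel) is missing or malformed."""


class InputSchemaError(InputError):
    """A tabular input does not match the canonical schema."""


class DegenerateDistributionError(CncEnumError, ValueError):
    """An automatic threshold cannot be derived from a degenerate distribution."""


class ReferencePopulationError(CncEnumError, ValueError):
    """The internal-control (leukocyte) reference population is too small."""


class PipelineStageError(CncEnumError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
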