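"""Exception hierarchy for the mosaicount pipeline."""


class MosaicountError(Exception):
    """Base class for all package errors."""


class AnnotationParseError(MosaicountError):
    """A row of an annotation file could not be parsed; names the line number."""

    def __init__(self, path, line_no, message):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class VocabularyError(MosaicountError):
    """A label outside the closed {adult, calf, ghost} vocabulary."""


class BoundsError(MosaicountError):
    """A box lies (partly) outside the mosaic or tile it is bound to."""


class FrameError(MosaicountError):
    """Two annotation sets refer to different mosaics/coordinate frames."""


class ConfigurationError(MosaicountError):
    """An invalid parameter combination (e.g. overlap >= tile size)."""


class UndefinedMetricError(MosaicountError):
    """A metric whose denominator is zero; explicitly not reported as 0."""


class CapacityError(MosaicountError):
    """Synthetic scene could not place the requested objects."""

    def __init__(self, message, achieved=None):
        self.achieved = achieved
        super().__init__(message)


class ObserverModelError(MosaicountError):
    """Inconsistent observer error model (probability rows not summing to 1)."""


class InputError(MosaicountError):
    """Malformed non-annotation input (empty raster, empty pool, ...)."""
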