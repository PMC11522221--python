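"""Exception hierarchy for the skelseg pipeline.

Every failure mode named in the module contracts maps to a distinct class so
callers (and the CLI) can react to specific conditions, e.g. skipping stretcher
removal on slices where no couch candidate exists.
"""


class SkelSegError(Exception):
    """Base class for all skelseg errors."""


class FileMissingError(SkelSegError, FileNotFoundError):
    """The requested volume path does not exist."""


class VolumeFormatError(SkelSegError):
    """The file exists but cannot be parsed as a supported image format."""


class NotThreeDimensionalError(SkelSegError):
    """The image payload does not have exactly three spatial axes."""


class NonNumericDataError(SkelSegError):
    """The image payload is not a numeric array (e.g. RGB or structured dtype)."""


class VolumeWriteError(SkelSegError, OSError):
    """The output path cannot be written."""


class NoStretcherError(SkelSegError):
    """No stretcher candidate was found in the left third of the binarized slice."""


class GeometryError(SkelSegError):
    """Phantom geometry constraints cannot be satisfied (e.g. bone outside body)."""


class DatasetError(SkelSegError):
    """Dataset construction failed (shape mismatch, too few slices, empty split)."""


class ConfigError(SkelSegError):
    """Invalid or unknown configuration key/value."""
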