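"""Exception hierarchy shared across the analysis stages."""


class ArteryNanoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ArteryNanoError):
    """Malformed or unsupported input file/array."""


class ProcessingError(ArteryNanoError):
    """A curve-processing stage could not be applied."""


class ContactNotFoundError(ProcessingError):
    """No tip-sample contact detectable in a force curve."""


class FitError(ProcessingError):
    """Hertz fit could not be performed on the given data."""


class EstimationError(ArteryNanoError):
    """Transform estimation or error evaluation is ill-posed."""


class RoiBoundsError(ArteryNanoError):
    """A region of interest falls (partly) outside the image."""


class ConfigError(ArteryNanoError):
    """Pipeline configuration does not validate."""
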