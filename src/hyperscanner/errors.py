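"""Exception hierarchy for the hyperscanner package."""


class HyperscannerError(Exception):
    """Base class for all package-specific errors."""


class EnviFormatError(HyperscannerError):
    """Malformed or incomplete ENVI header / data file."""


class MetadataError(HyperscannerError):
    """Header metadata inconsistent with the data payload."""


class ParameterError(HyperscannerError):
    """Spectrum/effect parameters outside their physical domain."""


class GeometryError(HyperscannerError):
    """Scene layout, crop margin or route outside the available extent."""


class CalibrationError(HyperscannerError):
    """White-reference or CV computation is undefined for the input."""


class EmptyBandMaskError(CalibrationError):
    """No band survived the CV threshold."""


class ConfigurationError(HyperscannerError):
    """A pipeline/analysis configuration is missing a required element."""


class EmptyInputError(HyperscannerError):
    """An operation received an empty pixel set or sample."""


class DegenerateSpectrumError(HyperscannerError):
    """A pixel spectrum cannot be normalized (zero Euclidean norm)."""


class EncodingError(HyperscannerError):
    """Controller instruction violates the binary instruction-set contract."""
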