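"""Exception hierarchy used across the package."""


class PhantomQcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhantomQcError):
    """A configuration value is invalid or inconsistent."""


class GeometryError(ConfigurationError):
    """A region or target does not fit where it was asked to go."""


class ImageReadError(PhantomQcError):
    """The input file could not be parsed as a phantom image."""


class LocalizationError(PhantomQcError):
    """Automatic ROI placement failed; manual placement is required."""


class MetricDomainError(PhantomQcError):
    """A metric is undefined for the given inputs (e.g. zero noise)."""


class CsvFormatError(PhantomQcError):
    """A QC record file is malformed."""
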