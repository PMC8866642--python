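"""Exception hierarchy shared across the pipeline stages."""


class PhotoacclimError(Exception):
    """Base class for all package errors."""


class InvalidReadError(PhotoacclimError):
    """A fluorescence read violates its physical preconditions (e.g. Fm' <= 0)."""


class DegenerateReadError(PhotoacclimError):
    """A quenching coefficient is undefined for this read (e.g. Fm' <= Fo')."""


class InsufficientDataError(PhotoacclimError):
    """Too few valid observations for the requested fit."""


class ParameterError(PhotoacclimError):
    """A model parameter is outside its admissible range."""


class SpectralCoverageError(PhotoacclimError):
    """A spectrum does not cover the wavelength band required by the operation."""


class SchemaError(PhotoacclimError):
    """A tabular input does not match its declared schema."""


class ConfigError(PhotoacclimError):
    """Invalid configuration (AF outside (0, 1], unknown keys, bad generator settings...)."""
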