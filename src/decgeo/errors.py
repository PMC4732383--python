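"""Exception hierarchy shared across the package."""


class DecGeoError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigurationError(DecGeoError, ValueError):
    """A model, scenario, or run configuration is internally inconsistent."""


class FormatError(DecGeoError, ValueError):
    """An on-disk file violates its expected format."""


class DataError(DecGeoError, ValueError):
    """Input data (tree, tip ranges) violate the analysis contract."""
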