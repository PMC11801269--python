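"""Exception hierarchy for the package."""


class FlexError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FlexError):
    """A file could not be parsed (non-numeric cell, bad header, ...)."""


class AlignmentError(FlexError):
    """Patient identifiers could not be aligned (duplicates, mismatches)."""


class MissingLabelError(FlexError):
    """A patient has modality data but no outcome label."""


class SchemaError(FlexError):
    """Feature names at apply time do not match those seen at fit time."""


class FitError(FlexError):
    """A preprocessing component could not be fitted (e.g. all-missing feature)."""


class ConfigError(FlexError):
    """An invalid or inconsistent configuration value."""


class UnsupportedCaseError(FlexError):
    """A case outside the model's stated capabilities (e.g. >1 missing modality)."""


class BackboneUnavailableError(ConfigError):
    """The requested image backbone is not bundled with this package."""
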