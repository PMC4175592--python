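"""Exception hierarchy used across the pipeline stages."""


class ClipscreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(ClipscreenError):
    """A configuration value is outside its permitted range."""


class GenerationError(ClipscreenError):
    """The simulator cannot produce output (e.g. zero total propensity)."""


class DesignError(ClipscreenError):
    """An experimental-design label or layout is invalid."""


class DataError(ClipscreenError):
    """Input data violate an input contract (missing barcode, empty input...)."""


class FormatError(ClipscreenError):
    """A file does not parse as the expected format."""
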