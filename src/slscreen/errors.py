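"""Exception types shared across the pipeline stages."""


class SlscreenError(Exception):
    """Base class for all package errors."""


class ModelParseError(SlscreenError):
    """A model file could not be parsed; the message names the offending element."""


class ConfigurationError(SlscreenError):
    """Invalid user configuration (missing objective, bad thresholds, bad order)."""


class InsufficientDataError(SlscreenError):
    """Too little data to fit the expression density (fewer than 100 nonzero genes)."""


class ContextInfeasibleError(SlscreenError):
    """A context-specific model cannot sustain biomass; names the context label."""
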