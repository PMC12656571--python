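"""Exception hierarchy shared across the pipeline."""


class ImuBreathError(Exception):
    """Base class for all package errors."""


class FormatError(ImuBreathError):
    """A file does not conform to the expected schema (missing columns, bad header)."""


class DataError(ImuBreathError):
    """A file parses but its content is invalid (overlapping intervals, non-monotone time)."""


class ConfigError(ImuBreathError):
    """A configuration or specification value is out of its valid range."""


class DegenerateDataError(ImuBreathError):
    """Data are structurally valid but unusable (constant channel, single-class split)."""
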