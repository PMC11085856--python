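"""Exception taxonomy shared across the pipeline."""


class GazefuseError(Exception):
    """Base class for all package errors."""


class ConfigError(GazefuseError, ValueError):
    """Invalid or incomplete configuration (e.g. a missing column mapping)."""


class DataError(GazefuseError, ValueError):
    """Malformed input data (e.g. non-monotone timestamps under strict policy)."""


class RangeError(GazefuseError, ValueError):
    """A value outside its documented domain (e.g. a time beyond the video)."""


class CapabilityError(GazefuseError, RuntimeError):
    """A requested backend or adapter is unavailable in this installation."""
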