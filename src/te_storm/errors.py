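"""Exception hierarchy shared across the pipeline stages."""


class TEStormError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(TEStormError, ValueError):
    """Invalid simulation or pipeline configuration."""


class InputError(TEStormError, ValueError):
    """Malformed input data (sequences, records, tracks)."""


class ConsistencyError(TEStormError, ValueError):
    """Cross-table consistency violation (ids missing, sets not nested)."""


class UsageError(TEStormError, ValueError):
    """Operation called with arguments that make the computation undefined."""
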