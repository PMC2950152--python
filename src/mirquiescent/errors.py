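"""Exception hierarchy shared across the pipeline stages."""


class MirquiescentError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirquiescentError, ValueError):
    """A file or container violates a structural invariant (duplicate ids, bad coordinates...)."""


class ParseError(FormatError):
    """A cell or field could not be interpreted; the message names the offending location."""


class ConsistencyError(MirquiescentError, ValueError):
    """Metadata contradicts itself (e.g. an inflammatory histological grade on a quiescent biopsy)."""


class ConfigError(MirquiescentError, ValueError):
    """An invalid configuration value or combination."""
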