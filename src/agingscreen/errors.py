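"""Exception hierarchy.

Errors are split so callers (and the CLI exit-code mapping) can tell apart
bad configuration, malformed input files, internally inconsistent data, and
statistical degeneracy (constant vectors, empty denominators).
"""


class AgingScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(AgingScreenError, ValueError):
    """Invalid configuration value or combination."""


class FormatError(AgingScreenError, ValueError):
    """A file does not conform to its declared format."""


class IntegrityError(AgingScreenError, ValueError):
    """Data is self-inconsistent (dimension mismatch, duplicates, ...)."""


class DegenerateDataError(AgingScreenError, ValueError):
    """A statistic is undefined on the given data (constant vector,
    empty denominator, zero variance in both groups, ...)."""


class DependencyError(AgingScreenError, RuntimeError):
    """A pipeline stage was requested without its upstream stage."""
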