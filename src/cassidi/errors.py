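"""Exception hierarchy used across the package.

All errors derive from :class:`ValueError` so callers that do not care about
the distinction can catch a single base class.
"""


class CassidiError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(CassidiError):
    """A file on disk does not conform to the expected format."""


class ParameterError(CassidiError):
    """A clustering/grid parameter is out of its valid range."""


class ConfigError(CassidiError):
    """A simulation configuration is internally inconsistent."""


class ConsistencyError(CassidiError):
    """Two inputs that must describe the same universe disagree."""


class AlignmentError(CassidiError):
    """Observed clusters cannot be unambiguously aligned to planted ones."""
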