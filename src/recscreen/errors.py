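"""Exception hierarchy shared across the package.

Validation/configuration problems (bad parameters, malformed tables,
inconsistent configs) all derive from :class:`RecscreenError` so the CLI can
map them to a single exit code, distinct from unexpected failures.
"""


class RecscreenError(Exception):
    """Base class for all anticipated errors raised by recscreen."""


class InvalidParameterError(RecscreenError, ValueError):
    """A numeric parameter violates its documented domain."""


class ConfigError(RecscreenError):
    """A configuration file or object is internally inconsistent."""


class ParseError(RecscreenError):
    """A tabular input failed schema validation; message names the row."""


class ViableCountError(RecscreenError):
    """A culture has no countable colonies on the permissive plate."""


class InsufficientReplicatesError(RecscreenError):
    """Too few replicate measurements for the requested statistic."""
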