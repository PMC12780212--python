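"""Exception hierarchy.

``HFError`` is the base for everything the pipeline can reject; the CLI maps
it to the data-error exit code.
"""


class HFError(Exception):
    """Base class for pipeline errors."""


class GridMismatchError(HFError):
    """Two layers do not share the same grid (or CRS)."""


class GeometryError(HFError):
    """A feature geometry is invalid or of the wrong kind."""


class ConfigError(HFError):
    """A run configuration is malformed or references missing data."""
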