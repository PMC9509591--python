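"""Exception hierarchy.

``DataError`` marks problems with user-supplied data (bad series, bad
geometry, bad config); the CLI maps it to exit code 3, while argument
misuse stays on click's exit code 2.
"""


class BonemapError(Exception):
    """Base class for all package errors."""


class DataError(BonemapError):
    """Invalid or inconsistent input data."""


class GeometryError(DataError):
    """A region of interest does not intersect the volume as required."""
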