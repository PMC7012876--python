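"""Exception hierarchy.

All package-specific failures derive from :class:`HemosysError` so callers
can catch one base class; the leaves additionally derive from the closest
builtin (ValueError / RuntimeError / FileNotFoundError) for ergonomic use
with generic handlers.
"""


class HemosysError(Exception):
    """Base class for all errors raised by hemosys."""


class FormatError(HemosysError, ValueError):
    """Input data violates the expected on-disk or in-memory layout."""


class SizeError(HemosysError, ValueError):
    """A series, window or image is too small for the requested operation."""


class CoverageError(HemosysError, ValueError):
    """A resampling bin or required time range has no data."""


class StateError(HemosysError, RuntimeError):
    """The pipeline is not in a state that allows the requested step."""


class MissingDataError(HemosysError, FileNotFoundError):
    """A required file or directory does not exist."""
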