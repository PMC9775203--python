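"""Exception hierarchy.

Every error raised by the library derives from :class:`FixBoxError`, so
callers (notably the command-line driver) can map failure categories to
exit codes without string matching.
"""

from __future__ import annotations


class FixBoxError(Exception):
    """Base class for all errors raised by this package."""


class SingularBoxError(FixBoxError):
    """The three primitive vectors are (numerically) coplanar."""


class GroParseError(FixBoxError):
    """A structure file could not be parsed.

    Parameters
    ----------
    message:
        Human-readable description of the defect.
    line_number:
        1-based line number in the input stream where the defect was found.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class GroWriteError(FixBoxError):
    """A configuration cannot be serialized (e.g. it has no atoms)."""


class DefsError(FixBoxError):
    """The definitions file is malformed or internally inconsistent."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class BoxExtentError(FixBoxError):
    """A centering set flagged E extends beyond one box length along an axis."""

    def __init__(self, axis: str, extent: float, snapshot: int | None = None):
        self.axis = axis
        self.extent = extent
        self.snapshot = snapshot
        where = f" (snapshot {snapshot})" if snapshot is not None else ""
        super().__init__(
            f"centering set extends beyond the box along {axis}{where}: "
            f"scaled extent {extent:.4f} > 1"
        )


class TopologyError(FixBoxError):
    """Two configurations do not share an atom count or molecule partition."""
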