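"""Exception hierarchy.

Every error a caller may want to branch on derives from :class:`CladepaintError`,
so ``except CladepaintError`` at the CLI boundary catches all domain failures
while programming errors (TypeError etc.) still propagate.
"""

from __future__ import annotations


class CladepaintError(Exception):
    """Base class for all domain errors raised by this package."""


class NewickParseError(CladepaintError):
    """Malformed Newick input; ``offset`` is the 0-based character offset."""

    def __init__(self, message: str, offset: int | None = None) -> None:
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class FileFormatError(CladepaintError):
    """Malformed record file; ``line`` is the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None, path: str | None = None) -> None:
        self.line = line
        self.path = path
        where = []
        if path is not None:
            where.append(str(path))
        if line is not None:
            where.append(f"line {line}")
        if where:
            message = f"{':'.join(where)}: {message}"
        super().__init__(message)


class NexusFormatError(CladepaintError):
    """Nexus document missing required blocks or internally inconsistent."""


class CladeMatchError(CladepaintError):
    """An event's clade matched no node of the tree (wrong tree/log pairing?)."""


class AnnotationError(CladepaintError):
    """Event placement failed: monotonicity violation or nothing matched."""


class ColorError(CladepaintError):
    """Malformed color override (must be '#rrggbb')."""
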