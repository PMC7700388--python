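"""Exception hierarchy for the memorient package."""


class MemorientError(Exception):
    """Base class for all package errors."""


class ConfigError(MemorientError):
    """Invalid run configuration or selection configuration."""


class ParseError(MemorientError):
    """Malformed record in a coordinate file.

    Carries the 1-based line number where parsing failed.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)


class StructuralError(MemorientError):
    """Trajectory-level inconsistency (e.g. atom count changes between frames)."""


class SelectionError(MemorientError):
    """A named selection resolved to an unexpected atom set."""


class DomainError(MemorientError, ValueError):
    """Arguments outside an operation's mathematical domain."""


class DegenerateBilayerError(DomainError):
    """Phosphate atoms do not form two separable leaflets."""


class FeasibilityError(DomainError):
    """Requested rigid-body placement is geometrically unattainable."""
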