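"""Exception hierarchy.

Every hard failure in the pipeline raises a subclass of
:class:`MethylspecError`, so callers (and the CLI) can catch one type and
map it to an exit code.
"""


class MethylspecError(Exception):
    """Base class for all package errors."""


class FormatError(MethylspecError):
    """A file does not conform to its declared format."""


class ParseError(FormatError):
    """A line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class RoleResolutionError(MethylspecError):
    """A role in the role map did not resolve to exactly one atom."""


class DegenerateGeometryError(MethylspecError):
    """A geometric construction is undefined (e.g. planar nitrogen)."""


class ParameterError(MethylspecError):
    """An argument violates its documented precondition."""


class EmptyDataError(MethylspecError):
    """No usable data (empty window, empty histogram, no samples on grid)."""


class NoBarrierError(MethylspecError):
    """A profile has no interior maximum between two minima."""


class ExtrapolationError(MethylspecError):
    """A correction curve does not span the profile grid."""


class ConfigError(MethylspecError):
    """Run-configuration validation failure; lists every offending key."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration: " + "; ".join(self.problems)
        )


class GeneratorError(MethylspecError):
    """A synthetic-data spec is infeasible."""
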