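"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`SarcoquantError`, so callers (and the CLI) can distinguish
expected validation failures from bugs.
"""


class SarcoquantError(Exception):
    """Base class for all package errors."""


class ValidationError(SarcoquantError):
    """A config or domain object violates its invariants."""


class ParseError(SarcoquantError):
    """A malformed input file. Carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class GeneSetError(SarcoquantError):
    """A gene-set operation cannot proceed (e.g. no set genes in the table)."""


class DensitometryError(SarcoquantError):
    """A lane quantification error (empty window, zero denominator, bad ladder)."""


class ProfileError(SarcoquantError):
    """An intensity-profile operation cannot proceed (too short, NaNs, sub-Nyquist)."""


class ConfigError(SarcoquantError):
    """A pipeline run-config fails schema validation; names the offending key."""
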