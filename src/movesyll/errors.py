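"""Exception hierarchy.

ValidationError covers malformed inputs (CLI exit code 2); ComputationError
covers numerical failures (exit code 3).
"""


class MoveSyllError(Exception):
    """Base class for all movesyll errors."""


class ValidationError(MoveSyllError):
    """Invalid input: bad shapes, out-of-range parameters, missing fields."""


class ComputationError(MoveSyllError):
    """A numerical step failed (e.g. singular system, degenerate design)."""
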