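"""Exception hierarchy for knetdist."""


class NetworkError(Exception):
    """Base class for all knetdist errors."""


class ValidationError(NetworkError):
    """A candidate graph violates a rooted-network invariant."""


class CycleError(ValidationError):
    """The edge relation contains a directed cycle."""


class MultiRootError(ValidationError):
    """The graph does not have exactly one in-degree-0 node."""


class LabelError(ValidationError):
    """Leaf-labelling is not a bijection (missing, duplicate, or misplaced label)."""


class DisconnectedError(ValidationError):
    """Some node is unreachable from the root."""


class ParseError(NetworkError):
    """Malformed eNewick or edge-list input."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class SizeError(NetworkError):
    """Input exceeds the configured bound of an exponential-time oracle."""


class GenerationError(NetworkError):
    """The random generator cannot satisfy the requested configuration."""


class ReductionDiverged(NetworkError):
    """Defensive guard: the reduction fixpoint loop exceeded its pass budget."""


class FixtureIntegrityError(NetworkError):
    """A transcribed figure network fails one of its documented facts."""
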