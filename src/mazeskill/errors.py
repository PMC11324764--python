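"""Exception types shared across the package."""


class MazeSkillError(Exception):
    """Base class for all package-specific errors."""


class LayoutError(MazeSkillError, ValueError):
    """A maze layout file is malformed or violates a named invariant."""


class OutOfBoundsError(MazeSkillError, ValueError):
    """A query point lies outside the maze bounds."""


class NoSectionError(MazeSkillError, ValueError):
    """A query point belongs to no section."""


class InfeasibleScriptError(MazeSkillError, ValueError):
    """A scripted primitive cannot be realised at the requested location."""


class InvalidCouplingError(MazeSkillError, ValueError):
    """A joint-coupling specification is not a valid correlation target."""


class AlignmentError(MazeSkillError, ValueError):
    """Two time series expected on one grid are misaligned."""


class InsufficientDataError(MazeSkillError, ValueError):
    """A series is too short for the requested analysis."""
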