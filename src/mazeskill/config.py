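"""Shared configuration for the maze-task analysis pipeline.

Every threshold that the rule-based primitive parser uses is defined here,
in one place, and the synthetic-trial generator reads the *same* constants,
so that generated ground truth and the parser's detections are governed by
a single set of rule parameters.

The ten cognitive primitives
----------------------------
A trial — one attempt to roll the sphere from the start to the target — is
described as an ordered sequence of labelled behavioural units:

====================  =========================================================
label                 behaviour
====================  =========================================================
``Guide``             sphere rolled between locations without touching a wall
``RollToCorner``      sphere rolls along a wall and stops when it meets another
``RollFromWall``      sphere leaves a wall it was rolling along
``InCorner``          sphere parked in a corner while the board is levelled
``RandomBounce``      repeated, apparently uncontrolled bounces off walls
``ControlledBounce``  a single deliberate bounce off a wall
``Steady``            wall-free excursion that returns near its starting point
``RollAlongWall``     sustained rolling contact with one wall
``RollToWall``        free approach that ends in rolling contact with a wall
``AtRest``            sphere motionless for at least a minimum dwell time
====================  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict

#: Canonical primitive labels, in the fixed order used throughout the package.
PRIMITIVES = (
    "Guide",
    "RollToCorner",
    "RollFromWall",
    "InCorner",
    "RandomBounce",
    "ControlledBounce",
    "Steady",
    "RollAlongWall",
    "RollToWall",
    "AtRest",
)

#: One-character codes for the symbolic trial string.  The map is a package
#: constant (documented here, stable across versions) and is invertible.
SYMBOLS: Dict[str, str] = {
    "Guide": "G",
    "RollToCorner": "C",
    "RollFromWall": "F",
    "InCorner": "I",
    "RandomBounce": "B",
    "ControlledBounce": "A",
    "Steady": "S",
    "RollAlongWall": "W",
    "RollToWall": "T",
    "AtRest": "R",
}
SYMBOLS_INVERSE = {v: k for k, v in SYMBOLS.items()}

#: Primitive labels that involve wall contact (used for contact metrics).
WALL_CONTACT_LABELS = frozenset(
    {"RollToCorner", "RollFromWall", "RandomBounce", "ControlledBounce",
     "RollAlongWall", "RollToWall"}
)

#: Sampling rate of the sphere tracker, the motion capture system and the
#: tactile stream (Hz).
FS_HZ = 200.0


@dataclass
class SegmentationParams:
    """Thresholds that operationalise the qualitative primitive definitions.

    Units are mm, seconds and degrees.  The defaults are the package's
    documented operating point; the task description defines the primitives
    only qualitatively, so all constants are configurable.

    Attributes
    ----------
    v_rest:
        Speed below which the sphere counts as motionless (mm/s).
    T_rest:
        Minimum dwell below ``v_rest`` for an AtRest segment (s).
    T_bounce_max:
        Wall-contact runs shorter than this are bounce-type (s).
    T_roll_min:
        Wall-contact runs at least this long are definite rolls (s); runs of
        intermediate duration are classed RollAlongWall (documented tie rule).
    r_corner_mm:
        Corner-proximity radius for InCorner / RollToCorner.  Note the sphere
        radius is 7.5 mm, so a ball wedged in a right-angle corner sits
        ~10.6 mm from the corner point; the default must exceed that.
    r_return_mm:
        A free segment whose endpoint returns within this distance of its
        start is Steady rather than Guide.
    r_approach_mm:
        Free-motion tail within this distance of the wall about to be
        contacted is RollToWall.
    r_depart_mm:
        Free-motion head within this distance of the wall just left is
        RollFromWall.
    level_tilt_deg:
        Both tilt angles must be below this for the board to count as level
        (InCorner).
    v_corner_max:
        Speed gate for InCorner: parking in a corner is slow; transits past a
        corner pocket at cruising speed are not InCorner (mm/s).
    n_random_bounce_min:
        Minimum number of bounce contacts, without leaving the section,
        for a merged RandomBounce.
    contact_tol_mm:
        Slack added to the sphere radius when testing wall contact.
    rest_lowpass_hz:
        Cutoff of the zero-phase Butterworth filter applied to raw speed
        before the rest threshold is applied (tracking noise makes raw
        instantaneous speed far too jittery for a 5 mm/s threshold).
    rest_gap_close_s:
        Sub-threshold gaps shorter than this are closed when merging rest
        intervals (absorbs isolated noise spikes).
    min_segment_samples:
        Final segments shorter than this merge into the longer neighbour.
    """

    v_rest: float = 5.0
    T_rest: float = 0.5
    T_bounce_max: float = 0.15
    T_roll_min: float = 0.25
    r_corner_mm: float = 15.0
    r_return_mm: float = 10.0
    r_approach_mm: float = 20.0
    r_depart_mm: float = 20.0
    level_tilt_deg: float = 2.0
    v_corner_max: float = 40.0
    n_random_bounce_min: int = 2
    contact_tol_mm: float = 1.0
    rest_lowpass_hz: float = 6.0
    rest_gap_close_s: float = 0.1
    min_segment_samples: int = 3

    def __post_init__(self) -> None:
        for name in ("v_rest", "T_rest", "T_bounce_max", "T_roll_min",
                     "r_corner_mm", "r_return_mm", "r_approach_mm",
                     "r_depart_mm", "level_tilt_deg", "v_corner_max",
                     "contact_tol_mm", "rest_lowpass_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SegmentationParams.{name} must be positive")
        if self.T_bounce_max >= self.T_roll_min:
            raise ValueError("T_bounce_max must be smaller than T_roll_min")
        if self.n_random_bounce_min < 2:
            raise ValueError("n_random_bounce_min must be at least 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        return cls(**d)


#: Printed per-primitive penalties.  Only wall-contact primitives carry a
#: nonzero penalty by default; RollToCorner / RollFromWall / InCorner have no
#: published value and default to zero (configurable).
DEFAULT_PENALTIES: Dict[str, float] = {
    "ControlledBounce": 0.03,
    "RandomBounce": 0.06,
    "RollAlongWall": 0.12,
    "RollToWall": 0.09,
    "RollToCorner": 0.0,
    "RollFromWall": 0.0,
    "InCorner": 0.0,
    "Guide": 0.0,
    "Steady": 0.0,
    "AtRest": 0.0,
}


@dataclass
class PenaltyTable:
    """Map primitive label -> penalty subtracted from the ideal score of 1."""

    penalties: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PENALTIES))

    def __post_init__(self) -> None:
        for label, pen in self.penalties.items():
            if label not in PRIMITIVES:
                raise ValueError(f"unknown primitive label {label!r}")
            if pen < 0:
                raise ValueError(f"penalty for {label!r} must be >= 0")

    def __getitem__(self, label: str) -> float:
        if label not in PRIMITIVES:
            raise KeyError(f"unknown primitive label {label!r}")
        return self.penalties.get(label, 0.0)

    def to_dict(self) -> dict:
        return dict(self.penalties)
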