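"""Rule-based parsing of sphere trajectories into cognitive primitives.

A trial — sphere position at 200 Hz plus the board tilt angles — is parsed
into an ordered, gapless sequence of the ten cognitive primitives by a
deterministic rule cascade.  The cascade works on per-sample evidence
(wall distances, section membership, corner proximity, filtered speed,
tilt) and claims samples in a fixed priority order:

1. **AtRest** — filtered speed below ``v_rest`` for at least ``T_rest``.
2. **InCorner** — within ``r_corner_mm`` of a wall junction with the board
   level (both tilt angles below ``level_tilt_deg``) and the sphere slow.
   Evaluated before the contact rules because a sphere parked in a corner
   is necessarily in contact with both walls.
3. Wall-contact runs — maximal contiguous runs of sphere-wall contact.
   Runs shorter than ``T_bounce_max`` are bounce-type; all longer runs are
   **RollAlongWall** (tie rule: intermediate durations count as rolls).
   A roll terminated in simultaneous contact with a second wall meeting
   the first at a corner has its terminal portion (within ``r_corner_mm``
   of the junction) relabelled **RollToCorner**.
4. Bounce grouping — ``n_random_bounce_min`` or more bounce contacts with
   no intervening section change merge, gaps included, into one
   **RandomBounce**; an isolated bounce is a **ControlledBounce**.
5. Free motion — the contiguous head of a free interval that follows a
   roll, while still within ``r_depart_mm`` of the departed wall, is
   **RollFromWall**; the contiguous tail within ``r_approach_mm`` of a
   wall about to be rolled along is **RollToWall**.
6. Remaining free motion is **Steady** if it ends within ``r_return_mm``
   of where it started, otherwise **Guide**.

All thresholds live in :class:`~mazeskill.config.SegmentationParams` and
are shared with the synthetic-trial generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .config import FS_HZ, PRIMITIVES, SYMBOLS, SYMBOLS_INVERSE, SegmentationParams
from .errors import AlignmentError
from .maze import MazeLayout, corner_set, wall_distances, sections_of

logger = logging.getLogger(__name__)

__all__ = [
    "SphereTrajectory", "TiltSeries", "ContactEvent", "PrimitiveSegment",
    "PrimitiveSegmentation", "detect_contacts", "detect_movement_onset",
    "detect_rest", "segment_trial", "to_symbol_string", "from_symbol_string",
    "label_samples", "labels_to_segmentation", "LABEL_CODE", "CODE_LABEL",
]

LABEL_CODE = {name: i for i, name in enumerate(PRIMITIVES)}
CODE_LABEL = {i: name for i, name in enumerate(PRIMITIVES)}


# ---------------------------------------------------------------------------
# time-series containers
# ---------------------------------------------------------------------------

@dataclass
class SphereTrajectory:
    """Planar sphere path on a uniform time grid."""

    t: np.ndarray          # seconds, uniform grid
    xy: np.ndarray         # (N, 2) mm
    fs: float = FS_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (len(self.t), 2):
            raise ValueError("trajectory arrays misshaped")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if steps.min() <= 0 or not np.allclose(steps, 1.0 / self.fs,
                                                   rtol=0, atol=1e-9):
                raise ValueError("t must increase with constant step 1/fs")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def speed(self) -> np.ndarray:
        """Per-sample planar speed (mm/s): central differences in the
        interior, one-sided at the ends."""
        v = np.gradient(self.xy, 1.0 / self.fs, axis=0)
        return np.linalg.norm(v, axis=1)


@dataclass
class TiltSeries:
    """Board attitude paired with a sphere trajectory (degrees)."""

    t: np.ndarray
    roll_deg: np.ndarray
    pitch_deg: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.roll_deg = np.asarray(self.roll_deg, dtype=float)
        self.pitch_deg = np.asarray(self.pitch_deg, dtype=float)
        if not (len(self.t) == len(self.roll_deg) == len(self.pitch_deg)):
            raise ValueError("tilt arrays must share one grid")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ContactEvent:
    """One maximal run of contact between the sphere and a single wall."""

    t_start: float
    t_end: float
    wall_id: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class PrimitiveSegment:
    label: str
    t_start: float
    t_end: float
    sections: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in PRIMITIVES:
            raise ValueError(f"unknown primitive label {self.label!r}")
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class PrimitiveSegmentation:
    """Ordered, gapless labelled segments over one trial."""

    trial_id: str
    segments: List[PrimitiveSegment]
    symbol_string: str = field(default="")

    def __post_init__(self) -> None:
        if not self.symbol_string:
            self.symbol_string = to_symbol_string(self)
        self.assert_partition()

    def assert_partition(self) -> None:
        segs = self.segments
        for a, b in zip(segs, segs[1:]):
            if not np.isclose(a.t_end, b.t_start, atol=1e-9):
                raise ValueError(
                    f"segments do not partition the trial: gap/overlap at "
                    f"{a.t_end} vs {b.t_start}")
        if len(self.symbol_string) != len(segs):
            raise ValueError("symbol string length != number of segments")

    @property
    def labels(self) -> List[str]:
        return [s.label for s in self.segments]

    @property
    def span(self) -> Tuple[float, float]:
        if not self.segments:
            return (0.0, 0.0)
        return (self.segments[0].t_start, self.segments[-1].t_end)


def to_symbol_string(segmentation: PrimitiveSegmentation) -> str:
    """One character per segment, using the package's fixed alphabet."""
    return "".join(SYMBOLS[s.label] for s in segmentation.segments)


def from_symbol_string(symbols: str) -> List[str]:
    """Invert :func:`to_symbol_string` back to a label sequence."""
    return [SYMBOLS_INVERSE[c] for c in symbols]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs (stop exclusive)."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _close_gaps(mask: np.ndarray, max_gap: int,
                boundary: bool = False) -> np.ndarray:
    """Fill False gaps of at most ``max_gap`` samples between True runs.

    With ``boundary`` True, short gaps touching the series ends are closed
    too (a noise blip at a trial boundary is not genuine motion)."""
    out = mask.copy()
    gaps = _runs(~mask)
    for a, b in gaps:
        if (a == 0 or b == len(mask)) and not boundary:
            continue
        if b - a <= max_gap:
            out[a:b] = True
    return out


def _lowpass_speed(speed: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass; falls back to the raw
    series when it is too short to filter."""
    if cutoff_hz >= fs / 2 or len(speed) < 25:
        return speed
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, speed)


# ---------------------------------------------------------------------------
# event detectors
# ---------------------------------------------------------------------------

def detect_contacts(trajectory: SphereTrajectory, layout: MazeLayout,
                    params: Optional[SegmentationParams] = None
                    ) -> List[ContactEvent]:
    """Per-wall contact events.

    Maximal contiguous runs of per-sample contact with the same wall become
    one event; runs shorter than 2 samples are dropped.  Rolling the sphere
    along a wall therefore yields a single event however long it lasts.
    """
    params = params or SegmentationParams()
    dists = wall_distances(layout, trajectory.xy)
    thr = layout.sphere_radius_mm + params.contact_tol_mm
    events: List[ContactEvent] = []
    for w in range(dists.shape[1]):
        for a, b in _runs(dists[:, w] <= thr):
            if b - a < 2:
                continue
            events.append(ContactEvent(t_start=float(trajectory.t[a]),
                                       t_end=float(trajectory.t[b - 1]),
                                       wall_id=w))
    events.sort(key=lambda e: (e.t_start, e.wall_id))
    return events


def detect_movement_onset(trajectory: SphereTrajectory,
                          box_mm: float = 20.0) -> float:
    """First time the sphere leaves the ``box_mm`` x ``box_mm`` axis-aligned
    box centred on its initial position.

    Mirrors the tracker's bounding-box onset rule (a ~20 mm x 20 mm box
    around the sphere's start).  Returns the end-of-trial time as a
    sentinel when the sphere never leaves the box.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    half = box_mm / 2.0
    dev = np.abs(trajectory.xy - trajectory.xy[0])
    outside = (dev[:, 0] > half) | (dev[:, 1] > half)
    idx = np.flatnonzero(outside)
    if idx.size == 0:
        return float(trajectory.t[-1])
    return float(trajectory.t[idx[0]])


def detect_rest(trajectory: SphereTrajectory,
                params: Optional[SegmentationParams] = None
                ) -> List[Tuple[float, float]]:
    """Maximal intervals with (filtered) speed below ``v_rest`` lasting at
    least ``T_rest`` seconds."""
    params = params or SegmentationParams()
    mask = _rest_mask(trajectory, params)
    return [(float(trajectory.t[a]), float(trajectory.t[b - 1]))
            for a, b in _runs(mask)]


def _slow_speed(trajectory: SphereTrajectory,
                params: SegmentationParams) -> np.ndarray:
    """Speed of the low-passed *position* track.

    Tracking noise rectifies into a positive speed offset if the magnitude
    is taken first, so for slow-motion thresholds the positions are
    filtered before differentiating."""
    n = len(trajectory)
    if n < 25 or params.rest_lowpass_hz >= trajectory.fs / 2:
        return trajectory.speed()
    sos = signal.butter(4, params.rest_lowpass_hz, btype="low",
                        fs=trajectory.fs, output="sos")
    xy_f = signal.sosfiltfilt(sos, trajectory.xy, axis=0)
    v = np.gradient(xy_f, 1.0 / trajectory.fs, axis=0)
    return np.linalg.norm(v, axis=1)


def _rest_mask(trajectory: SphereTrajectory,
               params: SegmentationParams) -> np.ndarray:
    speed = _slow_speed(trajectory, params)
    below = speed < params.v_rest
    below = _close_gaps(below, int(round(params.rest_gap_close_s * trajectory.fs)),
                        boundary=True)
    min_n = int(round(params.T_rest * trajectory.fs))
    mask = np.zeros_like(below)
    for a, b in _runs(below):
        if b - a >= min_n:
            mask[a:b] = True
    return mask


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

def segment_trial(trajectory: SphereTrajectory,
                  tilt: Optional[TiltSeries],
                  layout: MazeLayout,
                  params: Optional[SegmentationParams] = None,
                  trial_id: str = "trial") -> PrimitiveSegmentation:
    """Parse one trial into an ordered, gapless primitive sequence.

    ``tilt`` may be None, in which case the InCorner rule degrades to
    "near a corner and slower than ``v_rest``" (with a logged warning),
    since board attitude is then unavailable.
    """
    params = params or SegmentationParams()
    n = len(trajectory)
    if n < 2:
        raise ValueError("trajectory too short to segment")
    if tilt is not None:
        if len(tilt) != n or not np.allclose(tilt.t, trajectory.t, atol=1e-9):
            raise AlignmentError("trajectory and tilt grids are misaligned")

    labels = label_samples(trajectory, tilt, layout, params)
    secs = sections_of(layout, trajectory.xy)
    return labels_to_segmentation(labels, trajectory.t, secs, params, trial_id)


def label_samples(trajectory: SphereTrajectory,
                  tilt: Optional[TiltSeries],
                  layout: MazeLayout,
                  params: SegmentationParams) -> np.ndarray:
    """Per-sample primitive codes (index into :data:`PRIMITIVES`)."""
    n = len(trajectory)
    fs = trajectory.fs
    xy = trajectory.xy
    dists = wall_distances(layout, xy)                       # (N, M)
    thr = layout.sphere_radius_mm + params.contact_tol_mm
    contact = dists <= thr
    contact_any = contact.any(axis=1)
    speed_lp = _slow_speed(trajectory, params)

    corners = corner_set(layout)
    if corners:
        cpts = np.asarray([c.point for c in corners])
        cdist = np.linalg.norm(xy[:, None, :] - cpts[None, :, :], axis=-1)
        corner_dist = cdist.min(axis=1)
        corner_wall_pairs = {frozenset(c.wall_ids) for c in corners}
    else:
        corner_dist = np.full(n, np.inf)
        corner_wall_pairs = set()

    code = np.full(n, -1, dtype=np.int16)

    # rule 1: AtRest
    rest = _rest_mask(trajectory, params)
    code[rest] = LABEL_CODE["AtRest"]

    # rule 2: InCorner (before contact classing: a parked sphere touches walls)
    near_corner = corner_dist <= params.r_corner_mm
    if tilt is not None:
        level = ((np.abs(tilt.roll_deg) < params.level_tilt_deg)
                 & (np.abs(tilt.pitch_deg) < params.level_tilt_deg))
        incorner = near_corner & level & (speed_lp < params.v_corner_max) & ~rest
    else:
        logger.warning("no tilt series: InCorner degrades to "
                       "'near corner and slower than v_rest'")
        incorner = near_corner & (speed_lp < params.v_rest) & ~rest
    code[incorner] = LABEL_CODE["InCorner"]

    # rule 3: contact runs on unclaimed samples; 1-2 sample dropouts are
    # tracking flicker at the contact boundary, not genuine separations
    free_contact = contact_any & (code < 0)
    for ga, gb in _runs(~free_contact):
        if 0 < ga and gb < n and gb - ga <= 2 and (code[ga:gb] < 0).all():
            free_contact[ga:gb] = True
    bounce_runs: List[Tuple[int, int]] = []
    for a, b in _runs(free_contact):
        if b - a < 2:
            continue  # tracking glint, not a contact
        dur = (b - a) / fs
        if dur < params.T_bounce_max:
            bounce_runs.append((a, b))
            continue
        code[a:b] = LABEL_CODE["RollAlongWall"]
        # terminal corner: simultaneous contact with a second wall that
        # meets the primary wall at a corner
        end_walls = np.flatnonzero(contact[b - 1])
        hit_corner = any(frozenset((int(i), int(j))) in corner_wall_pairs
                         for k, i in enumerate(end_walls)
                         for j in end_walls[k + 1:])
        if hit_corner and corner_dist[b - 1] <= params.r_corner_mm:
            tail = b
            while tail > a and corner_dist[tail - 1] <= params.r_corner_mm:
                tail -= 1
            code[tail:b] = LABEL_CODE["RollToCorner"]

    # rule 4: bounce grouping by section continuity
    grouped: List[List[Tuple[int, int]]] = []
    secs = sections_of(layout, xy)
    for run in bounce_runs:
        if grouped:
            prev = grouped[-1][-1]
            between = slice(prev[1], run[0])
            same_section = np.all(secs[between] == secs[prev[1] - 1])
            unclaimed = np.all(code[between] < 0)
            if same_section and unclaimed:
                grouped[-1].append(run)
                continue
        grouped.append([run])
    for group in grouped:
        if len(group) >= params.n_random_bounce_min:
            code[group[0][0]:group[-1][1]] = LABEL_CODE["RandomBounce"]
        else:
            a, b = group[0]
            code[a:b] = LABEL_CODE["ControlledBounce"]

    # rules 5-6: free-motion intervals
    roll_codes = {LABEL_CODE["RollAlongWall"], LABEL_CODE["RollToCorner"]}
    for a, b in _runs(code < 0):
        lo, hi = a, b
        if a > 0 and int(code[a - 1]) in roll_codes:
            wall_ids = np.flatnonzero(contact[a - 1])
            if wall_ids.size:
                d_prev = dists[:, wall_ids].min(axis=1)
                while lo < hi and d_prev[lo] <= params.r_depart_mm:
                    lo += 1
                code[a:lo] = LABEL_CODE["RollFromWall"]
        if b < n and int(code[b]) in roll_codes:
            wall_ids = np.flatnonzero(contact[b])
            if wall_ids.size:
                d_next = dists[:, wall_ids].min(axis=1)
                while hi > lo and d_next[hi - 1] <= params.r_approach_mm:
                    hi -= 1
                code[hi:b] = LABEL_CODE["RollToWall"]
        if hi > lo:
            ret = np.linalg.norm(xy[hi - 1] - xy[lo])
            label = "Steady" if ret <= params.r_return_mm else "Guide"
            code[lo:hi] = LABEL_CODE[label]
    return code


def labels_to_segmentation(code: np.ndarray, t: np.ndarray,
                            secs: np.ndarray, params: SegmentationParams,
                            trial_id: str) -> PrimitiveSegmentation:
    """Run-length encode per-sample codes into a partition; final segments
    below ``min_segment_samples`` merge into the longer neighbour."""
    bounds = np.flatnonzero(np.diff(code)) + 1
    starts = np.concatenate(([0], bounds))
    stops = np.concatenate((bounds, [len(code)]))
    runs = [[int(a), int(b), int(code[a])] for a, b in zip(starts, stops)]

    changed = True
    while changed and len(runs) > 1:
        changed = False
        lengths = [r[1] - r[0] for r in runs]
        order = int(np.argmin(lengths))
        if lengths[order] < params.min_segment_samples:
            left = runs[order - 1] if order > 0 else None
            right = runs[order + 1] if order < len(runs) - 1 else None
            if left is not None and (right is None or
                                     (left[1] - left[0]) >= (right[1] - right[0])):
                left[1] = runs[order][1]
                del runs[order]
            else:
                right[0] = runs[order][0]
                del runs[order]
            # re-merge identical neighbours
            i = 0
            while i < len(runs) - 1:
                if runs[i][2] == runs[i + 1][2]:
                    runs[i][1] = runs[i + 1][1]
                    del runs[i + 1]
                else:
                    i += 1
            changed = True

    segments = []
    for a, b, c in runs:
        sec_run = secs[a:b]
        keep = np.concatenate(([True], np.diff(sec_run) != 0))
        t_end = float(t[b]) if b < len(t) else float(t[-1])
        segments.append(PrimitiveSegment(
            label=CODE_LABEL[int(c)],
            t_start=float(t[a]),
            t_end=t_end,
            sections=tuple(int(s) for s in sec_run[keep])))
    return PrimitiveSegmentation(trial_id=trial_id, segments=segments)
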