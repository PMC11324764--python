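"""Geometric model of the maze board.

The maze is a 170 mm x 150 mm board carrying thin interior walls, circular
pits, a start and a target location, and a tiling of the playable surface
into 21 numbered sections that the sphere tracker uses to localise the
15 mm sphere.  All downstream contact logic (wall contacts, corners,
section transitions) is driven by the queries in this module.

Coordinates live in a 2-D maze frame: origin at the lower-left playable
corner, +x toward the target side, units mm.  The board's 3-D attitude
(roll/pitch) is carried separately as a tilt time series and never enters
the planar geometry here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import List, Sequence, Set, Tuple

import numpy as np
import shapely
from shapely.geometry import Polygon, Point

from .errors import LayoutError, NoSectionError, OutOfBoundsError

__all__ = [
    "MazeLayout", "Corner", "Section", "Pit",
    "load_layout", "save_layout", "default_layout",
    "wall_distance", "wall_distances", "detect_wall_contact",
    "section_of", "sections_of", "corner_set",
]

_AREA_RTOL = 1e-6


@dataclass(frozen=True)
class Pit:
    cx: float
    cy: float
    r: float

    def contains(self, p: Sequence[float]) -> bool:
        return math.hypot(p[0] - self.cx, p[1] - self.cy) <= self.r


@dataclass(frozen=True)
class Section:
    id: int
    polygon: Tuple[Tuple[float, float], ...]
    adjacent: Tuple[int, ...]


@dataclass(frozen=True)
class Corner:
    """A wall junction: two walls sharing an endpoint within tolerance."""

    point: Tuple[float, float]
    wall_ids: Tuple[int, int]
    interior_angle: float  # degrees, in (0, 180)


@dataclass
class MazeLayout:
    """Walls, pits, sections and landmarks of the maze board.

    ``walls`` is a list of straight segments ``(x1, y1, x2, y2)`` indexed by
    position (wall id = list index).  ``sections`` tile the full board
    rectangle without overlap.
    """

    width_mm: float
    height_mm: float
    walls: List[Tuple[float, float, float, float]]
    pits: List[Pit]
    sections: List[Section]
    start: Tuple[float, float]
    target: Tuple[float, float]
    sphere_radius_mm: float = 7.5

    # caches, built lazily
    _wall_arr: np.ndarray = field(default=None, repr=False, compare=False)
    _polys: list = field(default=None, repr=False, compare=False)

    # -- derived geometry -------------------------------------------------
    @property
    def wall_array(self) -> np.ndarray:
        """Walls as an (M, 4) float array."""
        if self._wall_arr is None:
            self._wall_arr = np.asarray(self.walls, dtype=float).reshape(-1, 4)
        return self._wall_arr

    @property
    def section_polygons(self) -> list:
        if self._polys is None:
            self._polys = [Polygon(s.polygon) for s in self.sections]
        return self._polys

    def in_bounds(self, p: Sequence[float]) -> bool:
        return (0.0 <= p[0] <= self.width_mm) and (0.0 <= p[1] <= self.height_mm)

    # -- validation -------------------------------------------------------
    def validate(self) -> "MazeLayout":
        """Check all layout invariants; raise :class:`LayoutError` naming the
        first violated invariant."""
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise LayoutError("invariant 'positive board size' violated")
        if self.sphere_radius_mm <= 0:
            raise LayoutError("invariant 'positive sphere radius' violated")
        for i, (x1, y1, x2, y2) in enumerate(self.walls):
            for x, y in ((x1, y1), (x2, y2)):
                if not (0 <= x <= self.width_mm and 0 <= y <= self.height_mm):
                    raise LayoutError(
                        f"invariant 'wall endpoints within bounds' violated "
                        f"by wall {i} endpoint ({x}, {y})")
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise LayoutError("invariant 'unique section ids' violated")
        polys = self.section_polygons
        for p in polys:
            if not p.is_valid or p.area <= 0:
                raise LayoutError("invariant 'valid section polygons' violated")
        # pairwise non-overlap (interior intersection area ~ 0)
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                inter = polys[i].intersection(polys[j]).area
                if inter > _AREA_RTOL * min(polys[i].area, polys[j].area):
                    raise LayoutError(
                        f"invariant 'sections pairwise non-overlapping' "
                        f"violated by sections {ids[i]} and {ids[j]}")
        playable = self.width_mm * self.height_mm
        union = shapely.unary_union(polys).area
        if abs(union - playable) > _AREA_RTOL * playable:
            raise LayoutError(
                "invariant 'section union covers playable area' violated "
                f"(union {union:.6f} vs playable {playable:.6f})")
        for name, pt in (("start", self.start), ("target", self.target)):
            n = sum(poly.covers(Point(pt)) for poly in polys)
            if n < 1:
                raise LayoutError(
                    f"invariant '{name} lies in exactly one section' violated")
        for pit in self.pits:
            if sum(poly.contains(Point(pit.cx, pit.cy)) for poly in polys) != 1:
                raise LayoutError(
                    "invariant 'pit center lies in exactly one section' "
                    f"violated by pit at ({pit.cx}, {pit.cy})")
        return self

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "width_mm": self.width_mm,
            "height_mm": self.height_mm,
            "walls": [list(w) for w in self.walls],
            "pits": [{"cx": p.cx, "cy": p.cy, "r": p.r} for p in self.pits],
            "sections": [
                {"id": s.id, "polygon": [list(v) for v in s.polygon],
                 "adjacent": list(s.adjacent)}
                for s in self.sections
            ],
            "start": list(self.start),
            "target": list(self.target),
            "sphere_radius_mm": self.sphere_radius_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MazeLayout":
        try:
            layout = cls(
                width_mm=float(d["width_mm"]),
                height_mm=float(d["height_mm"]),
                walls=[tuple(float(v) for v in w) for w in d["walls"]],
                pits=[Pit(float(p["cx"]), float(p["cy"]), float(p["r"]))
                      for p in d["pits"]],
                sections=[
                    Section(int(s["id"]),
                            tuple(tuple(float(v) for v in xy)
                                  for xy in s["polygon"]),
                            tuple(int(a) for a in s.get("adjacent", ())))
                    for s in d["sections"]
                ],
                start=tuple(float(v) for v in d["start"]),
                target=tuple(float(v) for v in d["target"]),
                sphere_radius_mm=float(d.get("sphere_radius_mm", 7.5)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise LayoutError(f"malformed layout file: {exc}") from exc
        return layout.validate()


def load_layout(path) -> MazeLayout:
    """Load and validate a maze layout from a JSON file."""
    try:
        with open(path) as fh:
            d = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise LayoutError(f"malformed layout file {path}: {exc}") from exc
    return MazeLayout.from_dict(d)


def save_layout(layout: MazeLayout, path) -> None:
    Path(path).write_text(json.dumps(layout.to_dict(), indent=1))


def default_layout() -> MazeLayout:
    """The packaged 21-section maze.

    A representative reconstruction with the published outer dimensions
    (170 mm x 150 mm), 21 sections, two alternative paths (upper and lower
    corridor) and a pit on each path; the published material does not
    include an interior wall map, so the interior is an artifact choice
    documented in the layout file itself.
    """
    with resources.files("mazeskill.data").joinpath("default_maze.json").open() as fh:
        return MazeLayout.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# point-vs-geometry queries
# ---------------------------------------------------------------------------

def _segment_distances(points: np.ndarray, walls: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to each wall segment.

    Parameters
    ----------
    points : (N, 2) array
    walls : (M, 4) array of segments (x1, y1, x2, y2)

    Returns
    -------
    (N, M) array of distances.
    """
    P = points[:, None, :]                      # (N, 1, 2)
    A = walls[None, :, 0:2]                     # (1, M, 2)
    B = walls[None, :, 2:4]
    AB = B - A
    denom = np.einsum("nmk,nmk->nm", AB, AB)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.einsum("nmk,nmk->nm", P - A, AB) / denom
    t = np.clip(t, 0.0, 1.0)
    closest = A + t[..., None] * AB
    return np.linalg.norm(P - closest, axis=-1)


def wall_distances(layout: MazeLayout, points: np.ndarray) -> np.ndarray:
    """(N, M) distances from N points to all M walls (vectorised)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return _segment_distances(pts, layout.wall_array)


def wall_distance(layout: MazeLayout, p: Sequence[float]) -> Tuple[float, int]:
    """Distance from ``p`` to the nearest wall and that wall's id.

    Ties are broken by the lowest wall id.  Raises
    :class:`OutOfBoundsError` if ``p`` is outside the board.
    """
    if not layout.in_bounds(p):
        raise OutOfBoundsError(f"point {tuple(p)} outside layout bounds")
    d = wall_distances(layout, np.asarray(p, dtype=float))[0]
    wall_id = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    return float(d[wall_id]), wall_id


def detect_wall_contact(layout: MazeLayout, center: Sequence[float],
                        contact_tol_mm: float = 1.0) -> Set[int]:
    """Walls the sphere (centred at ``center``) is in contact with.

    Wall ``w`` is in contact iff its distance to the sphere centre is at
    most ``sphere_radius_mm + contact_tol_mm`` (boundary inclusive).
    """
    if not layout.in_bounds(center):
        raise OutOfBoundsError(f"point {tuple(center)} outside layout bounds")
    d = wall_distances(layout, np.asarray(center, dtype=float))[0]
    thr = layout.sphere_radius_mm + contact_tol_mm
    return set(np.flatnonzero(d <= thr).tolist())


def contact_mask(layout: MazeLayout, points: np.ndarray,
                 contact_tol_mm: float = 1.0) -> np.ndarray:
    """(N, M) boolean contact matrix for a whole trajectory (vectorised)."""
    d = wall_distances(layout, points)
    return d <= layout.sphere_radius_mm + contact_tol_mm


def sections_of(layout: MazeLayout, points: np.ndarray) -> np.ndarray:
    """Section id for each of N points (vectorised).

    Points on a shared boundary resolve to the lowest-id section
    (half-open convention).  Points in no section get id -1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    out = np.full(len(pts), -1, dtype=int)
    order = np.argsort([s.id for s in layout.sections])
    for idx in order[::-1]:  # high ids first; low ids overwrite => low id wins
        sec = layout.sections[idx]
        poly = layout.section_polygons[idx]
        covered = shapely.covers(poly, geoms)
        out[covered] = sec.id
    return out


def section_of(layout: MazeLayout, p: Sequence[float]) -> int:
    """Section id containing point ``p`` (lowest id wins on boundaries)."""
    sid = int(sections_of(layout, np.asarray(p, dtype=float))[0])
    if sid < 0:
        raise NoSectionError(f"point {tuple(p)} lies in no section")
    return sid


def corner_set(layout: MazeLayout, tol_corner_mm: float = 2.0,
               max_angle_deg: float = 175.0) -> List[Corner]:
    """Enumerate wall junctions.

    Every pair of walls with a shared endpoint (within ``tol_corner_mm``)
    yields exactly one :class:`Corner`; near-collinear continuations
    (interior angle above ``max_angle_deg``) are not corners.
    """
    walls = layout.wall_array
    corners: List[Corner] = []
    M = len(walls)
    for i in range(M):
        for j in range(i + 1, M):
            ei = [walls[i, 0:2], walls[i, 2:4]]
            ej = [walls[j, 0:2], walls[j, 2:4]]
            best = None
            for a in ei:
                for b in ej:
                    dist = float(np.hypot(*(a - b)))
                    if dist <= tol_corner_mm and (best is None or dist < best[0]):
                        best = (dist, a, b)
            if best is None:
                continue
            _, a, b = best
            pt = (a + b) / 2.0
            # directions away from the junction along each wall
            di = (ei[1] if np.allclose(a, ei[0]) else ei[0]) - a
            dj = (ej[1] if np.allclose(b, ej[0]) else ej[0]) - b
            ni, nj = np.linalg.norm(di), np.linalg.norm(dj)
            if ni == 0 or nj == 0:
                continue
            cosang = float(np.clip(np.dot(di, dj) / (ni * nj), -1.0, 1.0))
            angle = math.degrees(math.acos(cosang))
            if angle >= max_angle_deg:
                continue
            corners.append(Corner(point=(float(pt[0]), float(pt[1])),
                                  wall_ids=(i, j), interior_angle=angle))
    return corners


def corner_points(layout: MazeLayout, tol_corner_mm: float = 2.0) -> np.ndarray:
    """(K, 2) array of corner junction points (empty -> shape (0, 2))."""
    cs = corner_set(layout, tol_corner_mm)
    if not cs:
        return np.empty((0, 2))
    return np.asarray([c.point for c in cs], dtype=float)
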