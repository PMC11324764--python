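"""Thumb-pressure image analysis on the 16 x 16 tactile array.

Each thumb rests on a 16 x 16 taxel grid whose response values span
0-4095 counts (the sensor response is not linear in force, so analysis
stays in raw counts).  Frames are denoised with a median filter, averaged
into a per-trial (or per-day) mean pressure image, and the high-pressure
region is summarised by intensity-weighted image moments: the raw moments
give the centroid, the second central moments give a covariance whose
eigen-decomposition yields a k-sigma ellipse (axes, orientation, area in
taxel^2).  Day-wise ellipse areas are compared with a one-way ANOVA,
falling back to Mann-Whitney U when normality or group balance fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "GRID", "VMAX", "TactileFrame", "PressureMap", "PressureEllipse",
    "median_filter_frame", "mean_image", "pressure_ellipse", "compare_areas",
]

GRID = 16      # taxels per side
VMAX = 4095    # sensor response ceiling (counts)


def _check_grid(grid: np.ndarray, integer: bool = True) -> np.ndarray:
    arr = np.asarray(grid)
    if arr.shape != (GRID, GRID):
        raise ValueError(f"tactile grid must be {GRID}x{GRID}")
    if integer:
        if np.any((arr < 0) | (arr > VMAX)):
            raise ValueError(f"tactile values must lie in [0, {VMAX}]")
    elif np.any(arr < 0):
        raise ValueError("pressure values must be non-negative")
    return arr


@dataclass
class TactileFrame:
    """One raw 16 x 16 pressure frame from one thumb."""

    side: str                # "L" or "R"
    t: float                 # seconds
    grid: np.ndarray         # integer counts in [0, 4095]

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        self.grid = _check_grid(self.grid).astype(np.int32)


@dataclass
class PressureMap:
    """A mean pressure image (per trial or per day)."""

    side: str
    scope: str               # e.g. "trial" or "day"
    grid: np.ndarray         # non-negative reals

    def __post_init__(self) -> None:
        self.grid = _check_grid(np.asarray(self.grid, dtype=float),
                                integer=False)


@dataclass(frozen=True)
class PressureEllipse:
    """k-sigma moment ellipse of a high-pressure region.

    ``centroid`` is (row, col) in taxel units; axes are full lengths in
    taxels; ``area = pi * (major/2) * (minor/2)`` in taxel^2.
    """

    centroid: tuple
    major_axis: float
    minor_axis: float
    orientation: float       # degrees in (-90, 90]; 0 for isotropic regions
    area: float

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("axes must satisfy major >= minor > 0")


def median_filter_frame(frame, kernel: int = 3):
    """Median filter over a kernel x kernel neighbourhood, edges by
    reflection.  Output stays within the sensor range."""
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 3")
    if isinstance(frame, TactileFrame):
        filtered = ndimage.median_filter(frame.grid, size=kernel,
                                         mode="reflect")
        return TactileFrame(side=frame.side, t=frame.t, grid=filtered)
    arr = _check_grid(frame)
    return ndimage.median_filter(arr, size=kernel, mode="reflect")


def mean_image(frames: Sequence[TactileFrame], scope: str = "trial",
               kernel: int = 3) -> PressureMap:
    """Taxel-wise mean of median-filtered frames (one thumb)."""
    if not frames:
        raise ValueError("mean_image requires at least one frame")
    sides = {f.side for f in frames}
    if len(sides) != 1:
        raise ValueError(f"frames mix sides {sorted(sides)}")
    stack = np.stack([
        ndimage.median_filter(f.grid, size=kernel, mode="reflect")
        for f in frames]).astype(float)
    return PressureMap(side=sides.pop(), scope=scope, grid=stack.mean(axis=0))


def pressure_ellipse(pmap, region_frac: float = 0.5,
                     k_sigma: float = 2.0) -> PressureEllipse:
    """Centroid and k-sigma ellipse of the dominant high-pressure region.

    The region is the largest 4-connected component of taxels at or above
    ``region_frac`` times the image maximum (when several high-pressure
    regions exist, the dominant one is kept).  Moments are
    intensity-weighted over that region: raw moments give the centroid,
    second central moments the covariance; the ellipse's full axes are
    ``2 * k_sigma * sqrt(eigenvalue)`` and its area
    ``pi * (major/2) * (minor/2)``.
    """
    grid = pmap.grid if isinstance(pmap, PressureMap) else \
        _check_grid(np.asarray(pmap, dtype=float), integer=False)
    vmax = grid.max()
    if vmax <= 0:
        raise ValueError("empty region: map is all zero")
    mask = grid >= region_frac * vmax
    labels, nlab = ndimage.label(mask)  # default structure = 4-connectivity
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, nlab + 1))
    region = labels == (1 + int(np.argmax(sizes)))
    w = np.where(region, grid, 0.0)
    rows, cols = np.mgrid[0:GRID, 0:GRID]
    m00 = w.sum()
    r0 = float((w * rows).sum() / m00)
    c0 = float((w * cols).sum() / m00)
    mu20 = float((w * (rows - r0) ** 2).sum() / m00)
    mu02 = float((w * (cols - c0) ** 2).sum() / m00)
    mu11 = float((w * (rows - r0) * (cols - c0)).sum() / m00)
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 1e-12, None)
    lam_minor, lam_major = evals[0], evals[1]
    major = 2.0 * k_sigma * math.sqrt(lam_major)
    minor = 2.0 * k_sigma * math.sqrt(lam_minor)
    if (lam_major - lam_minor) / lam_major < 1e-6:
        orient = 0.0  # isotropic: orientation undefined, 0 by convention
    else:
        v = evecs[:, 1]  # (d_row, d_col) of the major axis
        orient = math.degrees(math.atan2(v[0], v[1]))
        if orient <= -90:
            orient += 180
        elif orient > 90:
            orient -= 180
    return PressureEllipse(centroid=(r0, c0), major_axis=major,
                           minor_axis=minor, orientation=orient,
                           area=math.pi * (major / 2) * (minor / 2))


def compare_areas(day1_areas: Sequence[float], day3_areas: Sequence[float],
                  normality_alpha: float = 0.05,
                  max_size_ratio: float = 1.5) -> Dict:
    """Compare per-trial ellipse areas between two days.

    A one-way two-group ANOVA (F with df (1, n1+n2-2)) is reported unless a
    Shapiro-Wilk pre-check rejects normality in either group or the group
    sizes are unbalanced beyond ``max_size_ratio``; then a Mann-Whitney U
    test (mid-ranks, normal approximation with tie correction) is used
    instead, flagged in ``test_used``.
    """
    a = np.asarray(day1_areas, dtype=float)
    b = np.asarray(day3_areas, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    means = {"day1": float(a.mean()), "day3": float(b.mean())}
    ratio = max(len(a), len(b)) / min(len(a), len(b))
    normal = True
    if np.ptp(a) > 0 and np.ptp(b) > 0:
        normal = (stats.shapiro(a).pvalue >= normality_alpha
                  and stats.shapiro(b).pvalue >= normality_alpha)
    if not normal or ratio > max_size_ratio:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        return {"test_used": "mann-whitney", "U": float(res.statistic),
                "F": None, "df1": None, "df2": None,
                "p": float(res.pvalue), "means": means}
    F, p = stats.f_oneway(a, b)
    return {"test_used": "anova", "F": float(F), "U": None,
            "df1": 1, "df2": len(a) + len(b) - 2,
            "p": float(p), "means": means}
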