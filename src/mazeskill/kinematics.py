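"""Joint-speed analysis: filtering, peak alignment and coordination.

The upper-body pipeline runs, in a fixed order: differentiate the 3-D
joint positions to speed magnitude, choose a low-pass cutoff automatically
from the raw speed by residual analysis, apply a 4th-order zero-phase
Butterworth filter, extract the 1-s window centred on each trial's peak
speed, and summarise per joint per day (pointwise mean and SEM).
Day-to-day change is tested per joint with a two-sample Kolmogorov-Smirnov
test, and inter-joint coordination with a Spearman rank-correlation matrix.

Zero-phase (forward-backward) filtering is deliberate: it does not shift
peaks in time, so peak-aligned averages stay aligned; its effective order
is twice the design order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from .config import FS_HZ
from .errors import AlignmentError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "JOINTS_8", "JOINTS_6", "JointTrack", "SpeedSeries", "AlignedWindow",
    "ProfileSummary", "compute_speed", "auto_cutoff", "lowpass",
    "peak_window", "summarize_profiles", "ks_compare", "spearman_matrix",
]

#: The eight tracked joint centres.
JOINTS_8 = ("LSho", "RSho", "LElb", "RElb", "LWri", "RWri", "LHip", "RHip")
#: The six key upper-body joints used for the coordination matrices.
JOINTS_6 = ("LSho", "RSho", "LElb", "RElb", "LWri", "RWri")


@dataclass
class JointTrack:
    """3-D position of one joint centre on a uniform 200 Hz grid (mm)."""

    joint: str
    t: np.ndarray
    xyz: np.ndarray
    fs: float = FS_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (len(self.t), 3):
            raise ValueError("xyz must be (N, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite positions")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, 1.0 / self.fs, rtol=0, atol=1e-9):
                raise AlignmentError("non-uniform time grid")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SpeedSeries:
    """Speed magnitude |v| of one joint (mm/s)."""

    joint: str
    t: np.ndarray
    v: np.ndarray
    fs: float = FS_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")
        if np.any(self.v < -1e-9):
            raise ValueError("speed magnitude must be non-negative")

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class AlignedWindow:
    """A 1-s speed excerpt centred on the trial's global peak.

    With ``half_s = 0.5`` at 200 Hz the window has 201 samples and the
    peak sits at centre index 100.
    """

    joint: str
    samples: np.ndarray
    peak_time: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        centre = (len(self.samples) - 1) // 2
        if int(np.argmax(self.samples)) != centre:
            raise ValueError("window max must sit at the centre sample")


@dataclass
class ProfileSummary:
    joint: str
    day: int
    mean: np.ndarray
    sem: np.ndarray
    n_windows: int


def compute_speed(track: JointTrack) -> SpeedSeries:
    """Differentiate positions (central differences interior, one-sided at
    the ends) and take the Euclidean norm of the three components."""
    if len(track) < 3:
        raise InsufficientDataError("need at least 3 samples to differentiate")
    vel = np.gradient(track.xyz, 1.0 / track.fs, axis=0)
    return SpeedSeries(joint=track.joint, t=track.t,
                       v=np.linalg.norm(vel, axis=1), fs=track.fs)


def auto_cutoff(v: SpeedSeries,
                candidates_hz: Optional[np.ndarray] = None,
                clamp: Optional[Tuple[float, float]] = None) -> float:
    """Automatic Butterworth cutoff by residual analysis.

    For each candidate cutoff the RMS residual between the raw and the
    filtered series is computed; a straight line fitted to the residuals
    over the high-frequency tail of the candidate grid estimates the noise
    floor, and the chosen cutoff is the smallest candidate whose residual
    falls within the projection of that noise line.  The result is clamped
    to [1, 0.25 * fs] Hz.
    """
    if len(v) < v.fs:
        raise InsufficientDataError("auto_cutoff needs at least 1 s of data")
    if candidates_hz is None:
        candidates_hz = np.arange(1.0, 20.0 + 1e-9, 0.5)
    lo, hi = clamp if clamp is not None else (1.0, 0.25 * v.fs)
    resid = np.array([
        np.sqrt(np.mean((v.v - lowpass(v.v, fc, fs=v.fs)) ** 2))
        for fc in candidates_hz])
    # noise asymptote from the top quarter of the candidate grid
    k = max(3, len(candidates_hz) // 4)
    tail_x, tail_y = candidates_hz[-k:], resid[-k:]
    b, a = np.polyfit(tail_x, tail_y, 1)
    projection = a + b * candidates_hz
    tol = 0.05 * max(resid.max(), 1e-12)
    ok = resid <= projection + tol
    chosen = float(candidates_hz[np.argmax(ok)]) if ok.any() else float(candidates_hz[-1])
    return float(np.clip(chosen, lo, hi))


def lowpass(v, cutoff: float, order: int = 4, fs: float = FS_HZ) -> np.ndarray:
    """4th-order Butterworth applied forward-backward (zero net phase,
    unit DC gain)."""
    arr = v.v if isinstance(v, SpeedSeries) else np.asarray(v, dtype=float)
    if not (0 < cutoff < fs / 2):
        raise ValueError(f"cutoff must lie in (0, fs/2), got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, arr)


def peak_window(v: SpeedSeries, half_s: float = 0.5) -> Optional[AlignedWindow]:
    """Extract the +/- ``half_s`` window around the global speed peak.

    Returns None (with a logged reason) when the peak lies within
    ``half_s`` of either trial boundary, so no full window exists.
    Ties are broken by the earliest peak.
    """
    if v.fs * 2 * half_s >= len(v):
        logger.info("trial too short for a %.2g s window: excluded", 2 * half_s)
        return None
    half_n = int(round(half_s * v.fs))
    peak = int(np.argmax(v.v))  # argmax -> earliest on ties
    if peak < half_n or peak + half_n >= len(v):
        logger.info("peak at t=%.3f s within %.2g s of a boundary: excluded",
                    v.t[peak], half_s)
        return None
    return AlignedWindow(joint=v.joint,
                         samples=v.v[peak - half_n:peak + half_n + 1],
                         peak_time=float(v.t[peak]))


def summarize_profiles(windows: Dict[Tuple[str, int], List[AlignedWindow]]
                       ) -> List[ProfileSummary]:
    """Pointwise mean and SEM per (joint, day) cell.

    Cells with fewer than 2 windows are skipped with a warning.
    """
    out: List[ProfileSummary] = []
    for (joint, day), ws in sorted(windows.items()):
        if len(ws) < 2:
            logger.warning("cell (%s, day %s) has %d window(s); skipped",
                           joint, day, len(ws))
            continue
        arr = np.stack([w.samples for w in ws])
        mean = arr.mean(axis=0)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(len(ws))
        out.append(ProfileSummary(joint=joint, day=day, mean=mean, sem=sem,
                                  n_windows=len(ws)))
    return out


def ks_compare(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_compare requires two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(speeds: Dict[str, np.ndarray],
                    joints: Sequence[str] = JOINTS_6) -> pd.DataFrame:
    """Spearman rank-correlation matrix of paired speed samples.

    ``speeds`` maps joint name to an equal-length 1-D speed series
    (typically filtered speeds concatenated over a day's included
    windows).  Ties are mid-ranked.
    """
    arrs = []
    n = None
    for j in joints:
        arr = np.asarray(speeds[j], dtype=float)
        if n is None:
            n = len(arr)
        elif len(arr) != n:
            raise AlignmentError("speed series must have equal length")
        arrs.append(arr)
    rho = stats.spearmanr(np.column_stack(arrs)).statistic
    if np.isscalar(rho):  # two joints
        rho = np.array([[1.0, rho], [rho, 1.0]])
    return pd.DataFrame(rho, index=list(joints), columns=list(joints))
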