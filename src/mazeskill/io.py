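"""Plain-text (CSV) readers and writers for the pipeline's data streams.

Formats
-------
trial trajectory   columns ``t_s, x_mm, y_mm, roll_deg, pitch_deg``
segment labels     columns ``t_start_s, t_end_s, label, sections``
                   (+ the symbol string in a ``.symbols.txt`` sidecar)
joint tracks       columns ``t_s, joint, x_mm, y_mm, z_mm``
tactile stream     columns ``t_s, side, v0..v255`` (row-major 16x16)
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import FS_HZ
from .kinematics import JointTrack
from .segmentation import (PrimitiveSegment, PrimitiveSegmentation,
                           SphereTrajectory, TiltSeries)
from .tactile import GRID, TactileFrame

__all__ = [
    "write_trial_csv", "read_trial_csv",
    "write_segments_csv", "read_segments_csv",
    "write_joint_tracks_csv", "read_joint_tracks_csv",
    "write_tactile_csv", "read_tactile_csv",
]


def write_trial_csv(path, trajectory: SphereTrajectory,
                    tilt: Optional[TiltSeries] = None) -> None:
    df = pd.DataFrame({
        "t_s": trajectory.t,
        "x_mm": trajectory.xy[:, 0],
        "y_mm": trajectory.xy[:, 1],
        "roll_deg": tilt.roll_deg if tilt is not None else np.nan,
        "pitch_deg": tilt.pitch_deg if tilt is not None else np.nan,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_trial_csv(path, fs: float = FS_HZ
                   ) -> Tuple[SphereTrajectory, Optional[TiltSeries]]:
    df = pd.read_csv(path)
    traj = SphereTrajectory(t=df["t_s"].to_numpy(),
                            xy=df[["x_mm", "y_mm"]].to_numpy(), fs=fs)
    tilt = None
    if "roll_deg" in df and df["roll_deg"].notna().all():
        tilt = TiltSeries(t=traj.t, roll_deg=df["roll_deg"].to_numpy(),
                          pitch_deg=df["pitch_deg"].to_numpy())
    return traj, tilt


def write_segments_csv(path, segmentation: PrimitiveSegmentation) -> None:
    df = pd.DataFrame({
        "t_start_s": [s.t_start for s in segmentation.segments],
        "t_end_s": [s.t_end for s in segmentation.segments],
        "label": [s.label for s in segmentation.segments],
        "sections": ["|".join(map(str, s.sections))
                     for s in segmentation.segments],
    })
    df.to_csv(path, index=False, float_format="%.4f")
    Path(path).with_suffix(".symbols.txt").write_text(
        segmentation.symbol_string + "\n")


def read_segments_csv(path, trial_id: str = "trial") -> PrimitiveSegmentation:
    df = pd.read_csv(path)
    segs = [
        PrimitiveSegment(
            label=row.label, t_start=float(row.t_start_s),
            t_end=float(row.t_end_s),
            sections=tuple(int(x) for x in str(row.sections).split("|")
                           if x not in ("", "nan")))
        for row in df.itertuples()
    ]
    return PrimitiveSegmentation(trial_id=trial_id, segments=segs)


def write_joint_tracks_csv(path, tracks: List[JointTrack]) -> None:
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "t_s": tr.t, "joint": tr.joint,
            "x_mm": tr.xyz[:, 0], "y_mm": tr.xyz[:, 1], "z_mm": tr.xyz[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.4f")


def read_joint_tracks_csv(path, fs: float = FS_HZ) -> List[JointTrack]:
    df = pd.read_csv(path)
    tracks = []
    for joint, grp in df.groupby("joint", sort=False):
        tracks.append(JointTrack(
            joint=str(joint), t=grp["t_s"].to_numpy(),
            xyz=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(), fs=fs))
    return tracks


def write_tactile_csv(path, frames: List[TactileFrame]) -> None:
    rows = {
        "t_s": [f.t for f in frames],
        "side": [f.side for f in frames],
    }
    flat = np.stack([f.grid.ravel() for f in frames]) if frames else \
        np.empty((0, GRID * GRID), dtype=int)
    for k in range(GRID * GRID):
        rows[f"v{k}"] = flat[:, k] if len(frames) else []
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tactile_csv(path) -> List[TactileFrame]:
    df = pd.read_csv(path)
    vcols = [f"v{k}" for k in range(GRID * GRID)]
    return [
        TactileFrame(side=str(row["side"]), t=float(row["t_s"]),
                     grid=row[vcols].to_numpy(dtype=int).reshape(GRID, GRID))
        for _, row in df.iterrows()
    ]
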