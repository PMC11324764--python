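"""End-to-end orchestration: simulate -> segment -> score -> curves ->
kinematics -> tactile, from a single config, with seeded reproducibility.

The pipeline writes tidy CSV outputs, basic plots (learning curve with its
95% confidence band, peak-aligned joint-speed profiles, the 6x6
coordination heatmaps, and thumb pressure heatmaps with the moment ellipse
overlaid) plus a manifest recording the config hash and seed: a manifest
fully determines a rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .config import PenaltyTable, SegmentationParams
from .errors import MazeSkillError
from .kinematics import (JOINTS_6, auto_cutoff, compute_speed, ks_compare,
                         lowpass, peak_window, spearman_matrix,
                         summarize_profiles)
from .maze import MazeLayout, default_layout, load_layout
from .scoring import day_accuracy, learning_curves, score_trial
from .segmentation import segment_trial
from .synthetic import (LearningModel, TrialGenParams, generate_joint_tracks,
                        generate_session, generate_tactile_stream,
                        tactile_day_blob)
from .tactile import compare_areas, mean_image, pressure_ellipse

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_DEFAULT_STAGES = ("simulate", "segment", "score", "curves",
                   "kinematics", "tactile")


@dataclasses.dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML."""

    seed: int = 0
    layout: Optional[str] = None          # path; None -> packaged default
    output_dir: str = "mazeskill_out"
    stages: tuple = _DEFAULT_STAGES
    days: tuple = (1, 2, 3)
    trials_per_day: int = 12
    kin_seconds_per_day: float = 30.0
    tactile_trials_per_day: int = 40
    tactile_frames_per_trial: int = 6
    learning_model: dict = dataclasses.field(default_factory=dict)
    penalties: dict = dataclasses.field(default_factory=dict)
    segmentation: dict = dataclasses.field(default_factory=dict)
    generator: dict = dataclasses.field(default_factory=dict)
    plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MazeSkillError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "days" in raw:
            raw["days"] = tuple(raw["days"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["days"] = list(d["days"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _load(cfg: PipelineConfig) -> MazeLayout:
    return load_layout(cfg.layout) if cfg.layout else default_layout()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the enabled stages in order and write the report bundle.

    Returns a dict of in-memory results keyed by stage.  On stage failure
    the partial outputs are retained and a :class:`MazeSkillError` naming
    the stage is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("mazeskill")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    layout = _load(config)
    results: Dict = {}
    try:
        stage = None
        for stage in config.stages:
            logger.info("stage %s starting", stage)
            _STAGES[stage](config, layout, out, results)
            logger.info("stage %s done", stage)
    except Exception as exc:
        raise MazeSkillError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "layout_hash": hashlib.sha256(
                json.dumps(layout.to_dict(), sort_keys=True).encode()
            ).hexdigest()[:16],
            "stages_completed": [s for s in config.stages if s in results],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        root_logger.removeHandler(handler)
        handler.close()
    return results


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, layout, out, results):
    model = LearningModel(**cfg.learning_model)
    gp = TrialGenParams(**cfg.generator)
    sp = SegmentationParams(**cfg.segmentation)
    sessions = []
    idx = 0
    for d_i, day in enumerate(cfg.days):
        sess = generate_session(layout, model=model,
                                n_trials=cfg.trials_per_day, day=day,
                                seed=cfg.seed * 1000 + d_i,
                                start_index=idx, params=gp, seg_params=sp)
        idx += cfg.trials_per_day
        sessions.append(sess)
        for i, tr in enumerate(sess.trials):
            mio.write_trial_csv(out / f"trial_d{day}_{i:03d}.csv",
                                tr.trajectory, tr.tilt)
    results["simulate"] = sessions


def _stage_segment(cfg, layout, out, results):
    sp = SegmentationParams(**cfg.segmentation)
    sessions = results.get("simulate") or []
    segmented = []
    for sess in sessions:
        per_day = []
        for i, tr in enumerate(sess.trials):
            seg = segment_trial(tr.trajectory, tr.tilt, layout, sp,
                                trial_id=tr.truth_segments.trial_id)
            mio.write_segments_csv(
                out / f"segments_d{sess.day}_{i:03d}.csv", seg)
            per_day.append(seg)
        segmented.append(per_day)
    results["segment"] = segmented


def _stage_score(cfg, layout, out, results):
    penalties = PenaltyTable({**PenaltyTable().penalties, **cfg.penalties})
    sessions = results.get("simulate") or []
    segmented = results.get("segment") or []
    rows = []
    idx = 0
    for sess, segs in zip(sessions, segmented):
        for i, (tr, seg) in enumerate(zip(sess.trials, segs)):
            ts = score_trial(seg, penalties, completed=tr.completed)
            rows.append({
                "trial_id": seg.trial_id, "participant": sess.participant_id,
                "day": sess.day, "index": idx, "score": ts.score,
                "n_contacts": ts.n_contacts,
                "contact_time_ratio": ts.contact_time_ratio,
                "completed": ts.completed,
            })
            idx += 1
    scores = pd.DataFrame(rows)
    scores.to_csv(out / "scores.csv", index=False)
    acc = {day: day_accuracy(list(grp["completed"]))
           for day, grp in scores.groupby("day")}
    pd.Series(acc, name="accuracy").rename_axis("day").to_csv(
        out / "day_accuracy.csv")
    results["score"] = scores


def _stage_curves(cfg, layout, out, results):
    scores = results.get("score")
    if scores is None or len(scores) < 3:
        logger.warning("curves: no scores available; skipped")
        return
    fits = learning_curves(scores, grouping="pooled")
    fits.update(learning_curves(scores, grouping="per-day"))
    rows = []
    for name, r in fits.items():
        frame = r.to_frame()
        frame["fit"] = name
        rows.append(frame)
        (out / f"regression_{name}.txt").write_text(r.summary() + "\n")
    pd.concat(rows).to_csv(out / "regressions.csv")
    if cfg.plots:
        _plot_curve(out, scores, fits["pooled"])
    results["curves"] = fits


def _stage_kinematics(cfg, layout, out, results):
    n = int(cfg.kin_seconds_per_day * 200)
    windows: Dict = {}
    day_speeds: Dict[int, Dict[str, np.ndarray]] = {}
    for day in (min(cfg.days), max(cfg.days)):
        tracks = generate_joint_tracks(n, day=day, seed=cfg.seed + day)
        speeds = {}
        for tr in tracks:
            sp = compute_speed(tr)
            fc = auto_cutoff(sp)
            # zero-phase filtering can ring slightly below zero on a
            # magnitude series; clip back to the physical range
            v = np.clip(lowpass(sp.v, fc, fs=sp.fs), 0.0, None)
            speeds[tr.joint] = v
            w = peak_window(dataclasses.replace(sp, v=v))
            if w is not None:
                windows.setdefault((tr.joint, day), []).append(w)
        day_speeds[day] = speeds
    profiles = summarize_profiles(windows)
    prof_rows = []
    for p in profiles:
        for i, (m, s) in enumerate(zip(p.mean, p.sem)):
            prof_rows.append({"joint": p.joint, "day": p.day, "idx": i,
                              "mean": m, "sem": s, "n": p.n_windows})
    pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
    d1, d3 = min(cfg.days), max(cfg.days)
    ks_rows = []
    for joint in day_speeds[d1]:
        D, p = ks_compare(day_speeds[d1][joint], day_speeds[d3][joint])
        ks_rows.append({"joint": joint, "D": D, "p": p})
    pd.DataFrame(ks_rows).to_csv(out / "ks_day_comparison.csv", index=False)
    mats = {}
    for day, speeds in day_speeds.items():
        mat = spearman_matrix({j: speeds[j] for j in JOINTS_6})
        mat.to_csv(out / f"correlation_day{day}.csv")
        mats[day] = mat
    if cfg.plots:
        _plot_kinematics(out, profiles, mats)
    results["kinematics"] = {"profiles": profiles, "ks": ks_rows,
                             "correlations": mats}


def _stage_tactile(cfg, layout, out, results):
    rows, maps = [], {}
    areas: Dict[tuple, List[float]] = {}
    for side in ("L", "R"):
        for day in cfg.days:
            blob = tactile_day_blob(day, side)
            day_frames = []
            for trial in range(cfg.tactile_trials_per_day):
                frames = generate_tactile_stream(
                    cfg.tactile_frames_per_trial, blob=blob, side=side,
                    seed=(cfg.seed * 7919 + day * 1009 + trial * 2
                          + (side == "R")) % (2 ** 31))
                pmap = mean_image(frames, scope="trial")
                ell = pressure_ellipse(pmap)
                rows.append({"trial": trial, "side": side, "day": day,
                             "c_row": ell.centroid[0], "c_col": ell.centroid[1],
                             "major": ell.major_axis, "minor": ell.minor_axis,
                             "orient_deg": ell.orientation, "area": ell.area})
                areas.setdefault((side, day), []).append(ell.area)
                day_frames.extend(frames)
            dmap = mean_image(day_frames, scope="day")
            maps[(side, day)] = dmap
            pd.DataFrame(dmap.grid).to_csv(
                out / f"tactile_heatmap_{side}_d{day}.csv", index=False)
    ellipses = pd.DataFrame(rows)
    ellipses.to_csv(out / "tactile_ellipses.csv", index=False)
    stats_rows = []
    d1, d3 = min(cfg.days), max(cfg.days)
    for side in ("L", "R"):
        res = compare_areas(areas[(side, d1)], areas[(side, d3)])
        res["side"] = side
        stats_rows.append({k: (json.dumps(v) if isinstance(v, dict) else v)
                           for k, v in res.items()})
    pd.DataFrame(stats_rows).to_csv(out / "tactile_area_stats.csv", index=False)
    if cfg.plots:
        _plot_tactile(out, maps)
    results["tactile"] = {"ellipses": ellipses, "stats": stats_rows}


_STAGES = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "score": _stage_score,
    "curves": _stage_curves,
    "kinematics": _stage_kinematics,
    "tactile": _stage_tactile,
}


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def _plot_curve(out, scores, fit):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(scores))
    ax.plot(x, scores["score"], ".", ms=3, alpha=0.5, label="trial score")
    order = np.argsort(fit.x)
    ax.plot(fit.x[order], fit.predict(fit.x[order]), "r-", label="OLS fit")
    ax.fill_between(fit.x[order], fit.ci95_lower[order], fit.ci95_upper[order],
                    color="r", alpha=0.2, label="95% CI")
    ax.set_xlabel("observation index")
    ax.set_ylabel("performance score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "learning_curve.png", dpi=110)
    plt.close(fig)


def _plot_kinematics(out, profiles, mats):
    plt = _mpl()
    joints = sorted({p.joint for p in profiles})
    fig, axes = plt.subplots(2, 4, figsize=(14, 6), sharex=True)
    tt = (np.arange(201) - 100) / 200.0
    for ax, joint in zip(axes.ravel(), joints):
        for p in profiles:
            if p.joint != joint:
                continue
            ax.plot(tt, p.mean, label=f"day {p.day}")
            ax.fill_between(tt, p.mean - p.sem, p.mean + p.sem, alpha=0.3)
        ax.set_title(joint)
    if axes[0, 0].get_legend_handles_labels()[0]:
        axes[0, 0].legend()
    fig.suptitle("peak-aligned joint speed (mean +/- SEM)")
    fig.tight_layout()
    fig.savefig(out / "joint_profiles.png", dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(mats), figsize=(6 * len(mats), 5))
    axes = np.atleast_1d(axes)
    for ax, (day, mat) in zip(axes, sorted(mats.items())):
        im = ax.imshow(mat.to_numpy(), vmin=0, vmax=1, cmap="YlOrRd")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=45)
        ax.set_yticks(range(len(mat)), mat.index)
        ax.set_title(f"day {day}")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.suptitle("joint-pair Spearman correlation")
    fig.tight_layout()
    fig.savefig(out / "correlations.png", dpi=110)
    plt.close(fig)


def _plot_tactile(out, maps):
    plt = _mpl()
    from matplotlib.patches import Ellipse
    sides = sorted({s for s, _ in maps})
    days = sorted({d for _, d in maps})
    fig, axes = plt.subplots(len(sides), len(days),
                             figsize=(4 * len(days), 4 * len(sides)))
    axes = np.atleast_2d(axes)
    for i, side in enumerate(sides):
        for j, day in enumerate(days):
            ax = axes[i, j]
            pmap = maps[(side, day)]
            ax.imshow(pmap.grid, cmap="hot")
            ell = pressure_ellipse(pmap)
            ax.add_patch(Ellipse((ell.centroid[1], ell.centroid[0]),
                                 width=ell.major_axis, height=ell.minor_axis,
                                 angle=-ell.orientation, fill=False,
                                 color="cyan", lw=2))
            ax.plot(ell.centroid[1], ell.centroid[0], "c+")
            ax.set_title(f"{side} thumb, day {day}")
    fig.tight_layout()
    fig.savefig(out / "thumb_pressure.png", dpi=110)
    plt.close(fig)
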