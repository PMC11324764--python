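"""Event detectors and the primitive rule cascade."""

import numpy as np
import pytest

from mazeskill.config import FS_HZ, SegmentationParams
from mazeskill.errors import AlignmentError
from mazeskill.maze import wall_distances
from mazeskill.segmentation import (PrimitiveSegment, PrimitiveSegmentation,
                                    SphereTrajectory, TiltSeries,
                                    detect_contacts, detect_movement_onset,
                                    detect_rest, from_symbol_string,
                                    segment_trial, to_symbol_string)
from mazeskill.synthetic import script_trial


def _traj(xy, fs=FS_HZ):
    xy = np.asarray(xy, dtype=float)
    return SphereTrajectory(t=np.arange(len(xy)) / fs, xy=xy, fs=fs)


class TestDetectContacts:
    def test_contact_free_trial_yields_nothing(self, layout):
        tr = script_trial(layout, ["Guide"], seed=11, finish="target")
        assert detect_contacts(tr.trajectory, layout) == []

    def test_scripted_roll_yields_single_event(self, layout, params):
        tr = script_trial(layout, ["RollAlongWall"], seed=3)
        truth_roll = [s for s in tr.truth_segments.segments
                      if s.label == "RollAlongWall"]
        events = detect_contacts(tr.trajectory, layout, params)
        # one wall, one maximal run covering the whole roll
        assert len({e.wall_id for e in events}) == 1
        longest = max(events, key=lambda e: e.duration)
        # the single event spans the ground-truth roll (plus the brief
        # in-contact fringe of the approach and departure legs)
        assert longest.duration == pytest.approx(
            sum(s.duration for s in truth_roll), abs=0.2)

    def test_matches_runlength_oracle(self, layout, params, rng):
        tr = script_trial(layout, ["RandomBounce", "RollAlongWall"], seed=8)
        events = detect_contacts(tr.trajectory, layout, params)
        d = wall_distances(layout, tr.trajectory.xy)
        thr = layout.sphere_radius_mm + params.contact_tol_mm
        expected = []
        for w in range(d.shape[1]):
            mask = d[:, w] <= thr
            runs, start = [], None
            for i, m in enumerate(mask):
                if m and start is None:
                    start = i
                elif not m and start is not None:
                    runs.append((start, i))
                    start = None
            if start is not None:
                runs.append((start, len(mask)))
            expected += [(w, a, b) for a, b in runs if b - a >= 2]
        got = [(e.wall_id,
                int(round(e.t_start * tr.trajectory.fs)),
                int(round(e.t_end * tr.trajectory.fs)) + 1) for e in events]
        assert sorted(got) == sorted(expected)


class TestMovementOnset:
    def test_stationary_returns_sentinel(self):
        tr = _traj(np.tile([50.0, 50.0], (400, 1)))
        assert detect_movement_onset(tr) == pytest.approx(tr.t[-1])

    def test_linear_motion_exits_at_half_width_over_speed(self):
        # 20 mm/s from the box centre: 10 mm half-width -> 0.5 s
        t = np.arange(400) / FS_HZ
        xy = np.column_stack([50.0 + 20.0 * t, np.full_like(t, 50.0)])
        assert detect_movement_onset(_traj(xy)) == pytest.approx(0.5, abs=0.01)

    def test_onset_robust_to_small_noise(self, rng):
        t = np.arange(400) / FS_HZ
        xy = np.column_stack([50.0 + 20.0 * t, np.full_like(t, 50.0)])
        clean = detect_movement_onset(_traj(xy))
        noisy = xy + rng.uniform(-0.9, 0.9, xy.shape) * (t < clean)[:, None]
        assert detect_movement_onset(_traj(noisy)) == pytest.approx(
            clean, abs=0.05)


class TestDetectRest:
    def test_motionless_trial_is_one_interval(self):
        tr = _traj(np.tile([50.0, 50.0], (600, 1)))
        intervals = detect_rest(tr)
        assert len(intervals) == 1
        a, b = intervals[0]
        assert b - a == pytest.approx(tr.duration, abs=0.01)

    def test_short_pause_is_ignored(self):
        t = np.arange(800) / FS_HZ
        x = np.where(t < 1.0, 40.0 + 60.0 * t,
                     np.where(t < 1.3, 100.0, 100.0 + 60.0 * (t - 1.3)))
        tr = _traj(np.column_stack([x, np.full_like(t, 75.0)]))
        for a, b in detect_rest(tr):
            assert b - a < 0.5 or pytest.fail("0.3 s pause counted as rest")

    def test_scripted_rest_duration_recovered(self, layout):
        tr = script_trial(layout, [("AtRest", {"duration": 2.0})], seed=5)
        intervals = detect_rest(tr.trajectory)
        assert len(intervals) == 1
        a, b = intervals[0]
        assert b - a == pytest.approx(2.0, abs=0.1)


class TestSegmentTrial:
    def test_guide_only(self, layout):
        tr = script_trial(layout, ["Guide"], seed=1, finish="target")
        seg = segment_trial(tr.trajectory, tr.tilt, layout)
        assert seg.labels == ["Guide"]

    def test_guide_bounce_guide(self, layout):
        tr = script_trial(layout, ["Guide", "ControlledBounce", "Guide"],
                          seed=2)
        seg = segment_trial(tr.trajectory, tr.tilt, layout)
        assert seg.labels == ["Guide", "ControlledBounce", "Guide"]

    def test_partition_property(self, layout):
        tr = script_trial(layout, ["Guide", "RandomBounce", "InCorner"],
                          seed=9, finish="target")
        seg = segment_trial(tr.trajectory, tr.tilt, layout)
        seg.assert_partition()
        assert seg.segments[0].t_start == pytest.approx(tr.trajectory.t[0])
        assert seg.segments[-1].t_end == pytest.approx(tr.trajectory.t[-1])

    def test_deterministic(self, layout):
        tr = script_trial(layout, ["Guide", "RollAlongWall"], seed=4)
        a = segment_trial(tr.trajectory, tr.tilt, layout)
        b = segment_trial(tr.trajectory, tr.tilt, layout)
        assert a.labels == b.labels
        assert [s.t_start for s in a.segments] == [s.t_start for s in b.segments]

    def test_misaligned_tilt_raises(self, layout):
        tr = script_trial(layout, ["Guide"], seed=1)
        bad = TiltSeries(t=tr.tilt.t[:-5], roll_deg=tr.tilt.roll_deg[:-5],
                         pitch_deg=tr.tilt.pitch_deg[:-5])
        with pytest.raises(AlignmentError):
            segment_trial(tr.trajectory, bad, layout)

    def test_monotone_rest_time_in_v_rest(self, layout):
        tr = script_trial(layout, ["Guide", "AtRest", "Guide"], seed=6)
        totals = []
        for v_rest in (3.0, 5.0, 9.0):
            p = SegmentationParams(v_rest=v_rest)
            tot = sum(b - a for a, b in detect_rest(tr.trajectory, p))
            totals.append(tot)
        assert totals == sorted(totals)

    def test_contact_samples_covered_by_contact_primitives(self, layout,
                                                           params):
        tr = script_trial(layout, ["RollAlongWall", "ControlledBounce"],
                          seed=13, finish="target")
        seg = segment_trial(tr.trajectory, tr.tilt, layout, params)
        contact_labels = {"RollAlongWall", "RollToCorner", "RollToWall",
                          "RollFromWall", "ControlledBounce", "RandomBounce",
                          "AtRest", "InCorner"}
        for e in detect_contacts(tr.trajectory, layout, params):
            for t_probe in (e.t_start + 0.01, (e.t_start + e.t_end) / 2):
                covering = [s for s in seg.segments
                            if s.t_start <= t_probe < s.t_end]
                assert covering and covering[0].label in contact_labels


class TestSymbols:
    def test_round_trip(self):
        seg = PrimitiveSegmentation(trial_id="x", segments=[
            PrimitiveSegment("Guide", 0.0, 1.0),
            PrimitiveSegment("RandomBounce", 1.0, 2.0),
            PrimitiveSegment("Guide", 2.0, 3.0),
        ])
        s = to_symbol_string(seg)
        assert len(s) == 3 and s[0] == s[2] == "G" and s[1] == "B"
        assert from_symbol_string(s) == ["Guide", "RandomBounce", "Guide"]

    def test_empty(self):
        seg = PrimitiveSegmentation(trial_id="x", segments=[])
        assert to_symbol_string(seg) == ""
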