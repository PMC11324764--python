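"""Contracts of the synthetic-data generators."""

import numpy as np
import pytest

from mazeskill.errors import InfeasibleScriptError, InvalidCouplingError
from mazeskill.kinematics import compute_speed
from mazeskill.maze import wall_distances
from mazeskill.scoring import score_trial
from mazeskill.segmentation import detect_contacts
from mazeskill.synthetic import (LearningModel, TrialGenParams,
                                 generate_joint_tracks, generate_session,
                                 sample_script, script_trial)


class TestScriptTrial:
    def test_deterministic_per_seed(self, layout):
        a = script_trial(layout, ["Guide", "RollAlongWall"], seed=21)
        b = script_trial(layout, ["Guide", "RollAlongWall"], seed=21)
        assert np.array_equal(a.trajectory.xy, b.trajectory.xy)
        assert np.array_equal(a.tilt.roll_deg, b.tilt.roll_deg)
        assert a.truth_segments.labels == b.truth_segments.labels

    def test_different_seeds_differ(self, layout):
        a = script_trial(layout, ["Guide"], seed=1, finish="target")
        b = script_trial(layout, ["Guide"], seed=2, finish="target")
        assert not np.array_equal(a.trajectory.xy, b.trajectory.xy)

    def test_guide_to_target_has_no_contact(self, layout, params):
        gp = TrialGenParams(noise_sd_mm=0.0, tilt_noise_sd_deg=0.0)
        tr = script_trial(layout, ["Guide"], params=gp, seed=1,
                          finish="target")
        assert tr.truth_segments.labels == ["Guide"]
        d = wall_distances(layout, tr.trajectory.xy).min(axis=1)
        assert d.min() > layout.sphere_radius_mm + params.contact_tol_mm
        assert np.allclose(tr.trajectory.xy[-1],
                           layout.target, atol=2.0)

    def test_scripted_rest_is_slow(self, layout):
        tr = script_trial(layout, [("AtRest", {"duration": 2.0})], seed=5)
        rest = [s for s in tr.truth_segments.segments if s.label == "AtRest"]
        assert rest and rest[0].duration == pytest.approx(2.0, abs=0.2)

    def test_controlled_bounce_single_contact_run(self, layout, params):
        tr = script_trial(layout, ["Guide", "ControlledBounce", "Guide"],
                          seed=2)
        events = detect_contacts(tr.trajectory, layout, params)
        assert len(events) == 1
        assert events[0].duration < params.T_bounce_max

    def test_trajectory_within_bounds(self, layout):
        tr = script_trial(layout, sample_script(np.random.default_rng(3)),
                          seed=3, finish="pit")
        xy = tr.trajectory.xy
        assert xy[:, 0].min() >= 0 and xy[:, 0].max() <= layout.width_mm
        assert xy[:, 1].min() >= 0 and xy[:, 1].max() <= layout.height_mm

    def test_pit_termination_ends_in_pit(self, layout):
        tr = script_trial(layout, ["Guide"], seed=4, finish="pit")
        assert not tr.completed
        end = tr.trajectory.xy[-1]
        assert any(np.hypot(end[0] - p.cx, end[1] - p.cy) <= p.r + 1.0
                   for p in layout.pits)

    def test_unknown_primitive_rejected(self, layout):
        with pytest.raises(InfeasibleScriptError, match="unknown"):
            script_trial(layout, ["Wobble"], seed=0)

    def test_steady_next_to_guide_rejected(self, layout):
        with pytest.raises(InfeasibleScriptError, match="Steady"):
            script_trial(layout, ["Guide", "Steady"], seed=0)

    def test_infeasible_roll_names_the_step(self, layout):
        # demanding an absurdly long clear rolling span is infeasible
        gp = TrialGenParams(roll_span=(500.0, 600.0))
        with pytest.raises(InfeasibleScriptError, match="step 0"):
            script_trial(layout, ["RollAlongWall"], params=gp, seed=0)


class TestLearningModel:
    def test_scores_clipped_to_unit_interval(self, rng):
        m = LearningModel(intercept=0.95, slope=0.0, resid_sd=0.3)
        y = m.draw_scores(500, rng)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            LearningModel(resid_sd=0.0)


class TestGenerateSession:
    def test_same_seed_identical(self, layout):
        a = generate_session(layout, n_trials=4, seed=9, realize="full")
        b = generate_session(layout, n_trials=4, seed=9, realize="full")
        for x, y in zip(a.trials, b.trials):
            assert np.array_equal(x.trajectory.xy, y.trajectory.xy)
            assert x.score == y.score and x.completed == y.completed

    def test_rescoring_truth_matches_intended_score(self, layout):
        sess = generate_session(layout, n_trials=10, seed=3, realize="full")
        for tr in sess.trials:
            got = score_trial(tr.truth_segments, completed=tr.completed)
            assert abs(got.score - tr.score) <= 0.015

    def test_perfect_model_yields_perfect_scores(self, layout):
        m = LearningModel(intercept=1.0, slope=0.0, resid_sd=1e-9)
        sess = generate_session(layout, model=m, n_trials=6, seed=1,
                                realize="full")
        for tr in sess.trials:
            assert score_trial(tr.truth_segments).score == pytest.approx(1.0)

    def test_scores_realization_matches_model(self, layout):
        from mazeskill.scoring import fit_ols
        sess = generate_session(layout, n_trials=1923, seed=11,
                                realize="scores")
        r = fit_ols(np.arange(1923.0), sess.scores())
        assert abs(r.beta1 - 0.0001016) <= 3 * r.se1

    def test_trial_order_contiguous(self, layout):
        sess = generate_session(layout, n_trials=5, seed=2, realize="scores")
        df = sess.scores_frame()
        assert list(df["index"]) == list(range(5))


class TestJointTracks:
    def test_identity_coupling_near_zero_offdiagonal(self):
        from mazeskill.kinematics import JOINTS_6, spearman_matrix
        tracks = generate_joint_tracks(20000, coupling=np.eye(8), seed=0)
        speeds = {t.joint: compute_speed(t).v for t in tracks}
        m = spearman_matrix(speeds, JOINTS_6).to_numpy()
        assert np.abs(m[~np.eye(6, dtype=bool)]).max() < 0.1

    def test_identical_drive_gives_unit_correlation(self):
        from scipy import stats
        C = np.ones((8, 8))
        tracks = generate_joint_tracks(4000, coupling=C, seed=1)
        v1 = compute_speed(tracks[0]).v
        v2 = compute_speed(tracks[1]).v
        assert stats.spearmanr(v1, v2).statistic == pytest.approx(1.0,
                                                                  abs=0.02)

    def test_target_three_quarters_recovered(self):
        from scipy import stats
        C = np.eye(8)
        C[0, 1] = C[1, 0] = 0.75
        tracks = generate_joint_tracks(10000, coupling=C, seed=2)
        rho = stats.spearmanr(compute_speed(tracks[0]).v,
                              compute_speed(tracks[1]).v).statistic
        assert 0.65 <= rho <= 0.85

    def test_peak_strictly_interior(self):
        for seed in range(5):
            tracks = generate_joint_tracks(3000, day=1, seed=seed)
            for t in tracks:
                peak = int(np.argmax(compute_speed(t).v))
                assert 0 < peak < len(t) - 1

    def test_asymmetric_coupling_rejected(self):
        C = np.eye(8)
        C[0, 1] = 0.5
        with pytest.raises(InvalidCouplingError, match="symmetric"):
            generate_joint_tracks(1000, coupling=C)

    def test_non_psd_coupling_rejected(self):
        C = np.eye(8)
        # a strongly contradictory triple is not a valid correlation matrix
        C[0, 1] = C[1, 0] = 0.9
        C[1, 2] = C[2, 1] = 0.9
        C[0, 2] = C[2, 0] = -0.9
        with pytest.raises(InvalidCouplingError, match="semi-definite"):
            generate_joint_tracks(1000, coupling=C)

    def test_day3_wrists_slow_while_others_speed_up(self):
        v1 = {t.joint: compute_speed(t).v.mean()
              for t in generate_joint_tracks(6000, day=1, seed=7)}
        v3 = {t.joint: compute_speed(t).v.mean()
              for t in generate_joint_tracks(6000, day=3, seed=7)}
        assert v3["LWri"] < v1["LWri"]
        assert v3["LSho"] > v1["LSho"]
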