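"""Speed computation, filtering, peak alignment and coordination stats."""

import numpy as np
import pytest

from mazeskill.config import FS_HZ
from mazeskill.errors import InsufficientDataError
from mazeskill.kinematics import (JOINTS_6, AlignedWindow, JointTrack,
                                  SpeedSeries, auto_cutoff, compute_speed,
                                  ks_compare, lowpass, peak_window,
                                  spearman_matrix, summarize_profiles)
from mazeskill.synthetic import generate_joint_tracks


def _track(xyz, joint="LWri"):
    xyz = np.asarray(xyz, dtype=float)
    return JointTrack(joint=joint, t=np.arange(len(xyz)) / FS_HZ, xyz=xyz)


def _speed(v, joint="LWri"):
    v = np.asarray(v, dtype=float)
    return SpeedSeries(joint=joint, t=np.arange(len(v)) / FS_HZ, v=v)


class TestComputeSpeed:
    def test_constant_position_zero_speed(self):
        sp = compute_speed(_track(np.tile([1.0, 2.0, 3.0], (100, 1))))
        assert np.allclose(sp.v, 0.0)

    def test_linear_motion_constant_speed(self):
        # 0.1 mm per sample at 200 Hz -> 20 mm/s
        xyz = np.column_stack([0.1 * np.arange(100), np.zeros(100),
                               np.zeros(100)])
        sp = compute_speed(_track(xyz))
        assert np.allclose(sp.v, 20.0)

    def test_circular_motion_matches_r_omega(self):
        r, omega = 50.0, 2 * np.pi * 1.0
        t = np.arange(2000) / FS_HZ
        xyz = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t),
                               np.zeros_like(t)])
        sp = compute_speed(_track(xyz))
        interior = sp.v[5:-5]
        assert np.allclose(interior, r * omega, rtol=0.005)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_speed(_track(np.zeros((2, 3))))


class TestAutoCutoff:
    def test_clean_low_frequency_signal_low_cutoff(self):
        t = np.arange(2000) / FS_HZ
        v = 100 + 50 * np.sin(2 * np.pi * 2.0 * t)
        assert auto_cutoff(_speed(np.abs(v))) <= 4.0

    def test_white_noise_clamps_low(self, rng):
        v = np.abs(rng.normal(0, 50, 2000))
        assert auto_cutoff(_speed(v)) == pytest.approx(1.0)

    def test_stability_under_added_noise(self, rng):
        t = np.arange(2000) / FS_HZ
        base = 100 + 50 * np.sin(2 * np.pi * 2.0 * t)
        fc0 = auto_cutoff(_speed(np.abs(base)))
        drops = 0
        for _ in range(100):
            noisy = np.abs(base + rng.normal(0, 5, len(base)))
            if auto_cutoff(_speed(noisy)) < fc0 - 0.5:
                drops += 1
        assert drops == 0

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            auto_cutoff(_speed(np.ones(100)))


class TestLowpass:
    def test_dc_gain_unity(self):
        out = lowpass(np.full(500, 7.0), cutoff=6.0)
        assert np.allclose(out, 7.0, atol=1e-9)

    def test_attenuates_high_frequency(self):
        t = np.arange(4000) / FS_HZ
        clean = np.sin(2 * np.pi * 1.0 * t)
        contaminated = clean + 1.0 * np.sin(2 * np.pi * 50.0 * t)
        out = lowpass(contaminated, cutoff=6.0)
        residual = out - lowpass(clean, cutoff=6.0)
        assert np.abs(residual[100:-100]).max() < 0.01  # > 99% attenuation

    def test_zero_phase_keeps_peak_location(self):
        # forward-backward filtering must not shift the speed peak in time
        t = np.arange(2000) / FS_HZ
        v = 100 * np.exp(-0.5 * ((t - 5.0) / 0.3) ** 2)
        out = lowpass(v, cutoff=6.0)
        assert int(np.argmax(out)) == int(np.argmax(v))

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.ones(100), cutoff=150.0)


class TestPeakWindow:
    def test_triangular_peak_centred(self):
        v = np.concatenate([np.linspace(0, 100, 300),
                            np.linspace(100, 0, 300)])
        w = peak_window(_speed(v))
        assert w is not None
        assert len(w.samples) == 201
        assert int(np.argmax(w.samples)) == 100

    def test_boundary_peak_excluded(self):
        v = np.concatenate([np.linspace(100, 0, 40),
                            np.zeros(400)])  # peak at t = 0
        assert peak_window(_speed(v)) is None

    def test_window_max_equals_series_max(self, rng):
        for _ in range(100):
            v = np.abs(lowpass(rng.normal(0, 50, 1200), cutoff=3.0))
            w = peak_window(_speed(v))
            if w is not None:
                assert w.samples.max() == pytest.approx(v.max())


class TestSummarize:
    def _win(self, samples):
        return AlignedWindow(joint="LWri", samples=samples, peak_time=1.0)

    def test_identical_windows_zero_sem(self):
        v = np.concatenate([np.arange(101), np.arange(99, -1, -1)]).astype(float)
        out = summarize_profiles({("LWri", 1): [self._win(v)] * 4})
        assert np.allclose(out[0].sem, 0.0)

    def test_two_windows_mean(self):
        base = np.concatenate([np.arange(101), np.arange(99, -1, -1)]).astype(float)
        out = summarize_profiles({("LWri", 1): [self._win(base),
                                                self._win(base * 3)]})
        assert np.allclose(out[0].mean, base * 2)

    def test_sem_shrinks_as_sqrt_n(self, rng):
        base = np.concatenate([np.arange(101), np.arange(99, -1, -1)]).astype(float)
        wins = [self._win(base + np.concatenate([
            rng.normal(0, 1, 100), [base[100] + 5], rng.normal(0, 1, 100)]))
            for _ in range(64)]
        s16 = summarize_profiles({("LWri", 1): wins[:16]})[0].sem.mean()
        s64 = summarize_profiles({("LWri", 1): wins})[0].sem.mean()
        assert s64 == pytest.approx(s16 / 2, rel=0.35)

    def test_single_window_cell_skipped(self):
        base = np.concatenate([np.arange(101), np.arange(99, -1, -1)]).astype(float)
        out = summarize_profiles({("LWri", 1): [self._win(base)]})
        assert out == []


class TestKsCompare:
    def test_identical_samples_zero_statistic(self):
        a = np.arange(50.0)
        D, p = ks_compare(a, a)
        assert D == pytest.approx(0.0)

    def test_disjoint_supports(self):
        D, p = ks_compare([1, 2, 3], [4, 5, 6])
        assert D == pytest.approx(1.0)

    def test_type_one_error_calibrated(self, rng):
        rej = sum(
            ks_compare(rng.standard_normal(200),
                       rng.standard_normal(200))[1] < 0.05
            for _ in range(2000))
        assert 0.035 <= rej / 2000 <= 0.065

    def test_power_monotone_in_shift(self, rng):
        powers = []
        for shift in (0.1, 0.3, 0.6):
            rej = sum(
                ks_compare(rng.standard_normal(150),
                           rng.standard_normal(150) + shift)[1] < 0.05
                for _ in range(200))
            powers.append(rej / 200)
        assert powers == sorted(powers) and powers[-1] > 0.95


class TestSpearmanMatrix:
    def test_self_correlation_and_symmetry(self, rng):
        speeds = {j: np.abs(rng.normal(0, 1, 500)) for j in JOINTS_6}
        m = spearman_matrix(speeds)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)

    def test_monotone_transform_invariance(self, rng):
        base = np.abs(rng.normal(0, 1, 500))
        speeds = {j: base if i == 0 else np.exp(base) if i == 1
                  else np.abs(rng.normal(0, 1, 500))
                  for i, j in enumerate(JOINTS_6)}
        m = spearman_matrix(speeds)
        assert m.iloc[0, 1] == pytest.approx(1.0)

    def test_generator_coupling_recovered(self):
        C = np.eye(8)
        C[0, 1] = C[1, 0] = 0.75
        tracks = generate_joint_tracks(10000, coupling=C, seed=2)
        speeds = {t.joint: compute_speed(t).v for t in tracks}
        m = spearman_matrix(speeds)
        assert 0.65 <= m.loc["LSho", "RSho"] <= 0.85

    def test_rank_psd(self, rng):
        tracks = generate_joint_tracks(4000, day=1, seed=5)
        speeds = {t.joint: compute_speed(t).v for t in tracks}
        m = spearman_matrix(speeds).to_numpy()
        assert np.linalg.eigvalsh(m).min() > -1e-8

    def test_length_mismatch_raises(self, rng):
        speeds = {j: np.ones(100) for j in JOINTS_6}
        speeds["RWri"] = np.ones(99)
        with pytest.raises(Exception):
            spearman_matrix(speeds)
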