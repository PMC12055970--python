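"""Feature detection and KLT tracking against closed-form motions and a
brute-force integer-shift SSD search oracle."""

import numpy as np
import pytest

import needlecav as nc
from needlecav.core import VideoSequence
from needlecav.synthetic import IntensityModel, SyntheticScene, static_motion
from needlecav.tracking import Trajectory

BG, FG = 220, 30


def square_frames(n_frames, shift_per_frame=0.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, 120, 120), np.uint8)
    for k in range(n_frames):
        f = np.full((120, 120), float(BG))
        s = int(round(k * shift_per_frame))
        f[30:70, 25 + s : 65 + s] = FG
        if noise_sd:
            f = f + rng.normal(0, noise_sd, f.shape)
        frames[k] = np.clip(f, 0, 255)
    return frames


class TestDetectFeatures:
    def test_dark_square_corners_are_strongest(self):
        pts = nc.detect_features(square_frames(1)[0], max_features=4)
        found = {(round(p.row), round(p.col)) for p in pts}
        true_corners = {(30, 25), (30, 64), (69, 25), (69, 64)}
        # each detection within 2 px of a distinct true corner
        assert len(found) == 4
        for r, c in found:
            assert min(abs(r - tr) + abs(c - tc) for tr, tc in true_corners) <= 4

    def test_uniform_frame_yields_no_features(self):
        assert nc.detect_features(np.full((64, 64), BG, np.uint8)) == []

    def test_ordering_is_deterministic(self):
        f = square_frames(1)[0]
        a = nc.detect_features(f)
        b = nc.detect_features(f)
        assert [(p.row, p.col, p.score) for p in a] == [
            (p.row, p.col, p.score) for p in b
        ]

    def test_stylet_tip_among_top_features_in_roi(self):
        scene = SyntheticScene(
            needle_geometry="side_cut",
            motion_profile=static_motion(),
            duration_s=3e-5,
            time_start_s=0.0,
            intensity=IntensityModel(noise_sd=0.0),
        )
        video, truth = nc.generate_video(scene)
        tip = truth.tip_positions_px["stylet_tip"][0]
        r, c = int(tip[0]), int(tip[1])
        pts = nc.detect_features(
            video.frames[0], roi=(r - 30, r + 20, c - 40, c + 40), max_features=5
        )
        dists = [np.hypot(p.row - tip[0], p.col - tip[1]) for p in pts]
        assert min(dists) <= 5.0

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="roi"):
            nc.detect_features(np.zeros((32, 32)), roi=(0, 64, 0, 64))


class TestTrackKLT:
    def test_static_scene_is_stationary(self):
        frames = square_frames(6, 0.0, noise_sd=0.0)
        video = VideoSequence(frames, 100_000, 25.0)
        seeds = nc.detect_features(frames[0], max_features=4)
        for traj in nc.track_klt(video, seeds):
            assert traj.valid.all()
            drift = np.abs(traj.positions - traj.positions[0]).max()
            assert drift <= 0.1

    def test_static_scene_with_noise_stays_subpixel(self):
        frames = square_frames(6, 0.0, noise_sd=5.0, seed=1)
        video = VideoSequence(frames, 100_000, 25.0)
        seeds = nc.detect_features(frames[0], max_features=4)
        for traj in nc.track_klt(video, seeds):
            assert traj.valid.all()
            assert np.abs(traj.positions - traj.positions[0]).max() <= 0.5

    def test_two_pixel_translation_recovered(self):
        frames = square_frames(6, 2.0)
        video = VideoSequence(frames, 100_000, 25.0)
        seeds = nc.detect_features(frames[0], max_features=4)
        for traj in nc.track_klt(video, seeds):
            steps = np.diff(traj.positions[:, 1])
            np.testing.assert_allclose(steps, 2.0, atol=0.1)
            np.testing.assert_allclose(np.diff(traj.positions[:, 0]), 0.0, atol=0.1)

    def test_agrees_with_exhaustive_ssd_oracle(self):
        """KLT displacement within 0.5 px of a brute-force integer-shift SSD
        search on 5-frame clips of the moving silhouette."""
        scene = SyntheticScene(
            needle_geometry="side_cut",
            motion_profile=nc.MotionProfile(
                y_fn=lambda t: 0.055 * (t * 1e5),  # 2.2 px/frame rightward
                z_fn=lambda t: np.zeros_like(t),
            ),
            duration_s=5e-5,
            time_start_s=0.0,
            intensity=IntensityModel(noise_sd=0.0),
        )
        video, truth = nc.generate_video(scene)
        tip = truth.tip_positions_px["stylet_tip"][0]
        seeds = nc.detect_features(
            video.frames[0],
            roi=(int(tip[0]) - 25, int(tip[0]) + 15, int(tip[1]) - 30, int(tip[1]) + 30),
            max_features=2,
        )
        trajs = nc.track_klt(video, seeds)
        half = 7
        for traj in trajs:
            assert traj.valid.all()
            for k in range(1, 5):
                r0, c0 = traj.positions[k - 1]
                ri, ci = int(round(r0)), int(round(c0))
                patch = video.frames[k - 1][
                    ri - half : ri + half + 1, ci - half : ci + half + 1
                ].astype(float)
                best, best_shift = np.inf, (0, 0)
                for dr in range(-5, 6):
                    for dc in range(-5, 6):
                        cand = video.frames[k][
                            ri + dr - half : ri + dr + half + 1,
                            ci + dc - half : ci + dc + half + 1,
                        ].astype(float)
                        ssd = np.sum((patch - cand) ** 2)
                        if ssd < best:
                            best, best_shift = ssd, (dr, dc)
                klt_step = traj.positions[k] - traj.positions[k - 1]
                assert abs(klt_step[0] - best_shift[0]) <= 0.5
                assert abs(klt_step[1] - best_shift[1]) <= 0.5


class TestKinematics:
    rate = 100_000.0

    def _traj(self, rows, cols):
        pos = np.stack([rows, cols], axis=1)
        return Trajectory(0, pos, np.ones(len(rows), bool))

    def test_constant_position_zero_velocity(self):
        n = 50
        k = nc.kinematics(
            self._traj(np.full(n, 40.0), np.full(n, 60.0)), self.rate, 25.0
        )
        np.testing.assert_allclose(k.vy, 0.0, atol=1e-12)
        np.testing.assert_allclose(k.az, 0.0, atol=1e-9)

    def test_one_pixel_per_frame_is_2p5_ms(self):
        """25 µm/frame at 100 kfps = 2.5 m/s."""
        n = 100
        k = nc.kinematics(
            self._traj(np.full(n, 40.0), 10 + np.arange(n, dtype=float)),
            self.rate,
            25.0,
        )
        assert np.median(k.vy) == pytest.approx(2.5, rel=1e-2)

    def test_quadratic_motion_recovers_acceleration(self):
        """z = a t²/2 with a = 8 m/s² sampled at 100 kHz -> 8 ± 0.1 m/s²."""
        n = 200
        t = np.arange(n) / self.rate
        rows = 100.0 - 0.5 * 8.0 * t**2 / 25e-6
        k = nc.kinematics(self._traj(rows, np.full(n, 30.0)), self.rate, 25.0)
        interior = slice(10, -10)
        np.testing.assert_allclose(k.az[interior], 8.0, atol=0.1)

    def test_velocity_integrates_back_to_displacement(self):
        """Round trip for a smooth motion: cumulative trapezoid of the
        velocity recovers the (smoothed) displacement within 1%."""
        n = 400
        t = np.arange(n) / self.rate
        y_mm = 0.5 * np.sin(2 * np.pi * 1000 * t)
        cols = 60 + y_mm / 25e-3
        k = nc.kinematics(self._traj(np.full(n, 40.0), cols), self.rate, 25.0)
        from scipy.integrate import cumulative_trapezoid

        rebuilt_mm = cumulative_trapezoid(k.vy, dx=1 / self.rate, initial=0.0) * 1e3
        scale = np.abs(k.y_mm).max()
        assert np.abs(rebuilt_mm - (k.y_mm - k.y_mm[0]))[10:-10].max() <= 0.01 * scale

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="3 valid frames"):
            nc.kinematics(self._traj(np.array([1.0, 2.0]), np.array([1.0, 2.0])), 1e5, 25.0)


class TestMotionEvents:
    rate = 100_000.0

    def _kin_from_cols(self, cols, smoothing=1):
        pos = np.stack([np.full(len(cols), 50.0), cols], axis=1)
        traj = Trajectory(0, pos, np.ones(len(cols), bool))
        return nc.kinematics(traj, self.rate, 25.0, smoothing=smoothing)

    def test_single_upward_crossing_on_monotone_ramp(self):
        n = 200
        t = np.arange(n) / self.rate
        v = 10.0 * t / t[-1]  # ramps 0 -> 10 m/s
        cols = 30 + np.cumsum(v) / self.rate / 25e-6
        kin = self._kin_from_cols(cols)
        events = nc.detect_motion_events(kin, v_threshold=7.0)
        ups = [c for c in events.crossings if c[1] == "y" and abs(c[2]) > 7.0]
        assert len(ups) == 1

    def test_no_crossings_below_threshold(self):
        """Velocities below 5.5 m/s produce no crossings at that threshold."""
        n = 200
        t = np.arange(n) / self.rate
        v = 5.0 * np.sin(2 * np.pi * 500 * t) ** 2  # peaks at 5 m/s
        cols = 30 + np.cumsum(v) / self.rate / 25e-6
        kin = self._kin_from_cols(cols)
        assert nc.detect_motion_events(kin, v_threshold=5.5).crossings == []

    def test_stop_time_at_programmed_stop(self):
        """Ramp to 10 m/s then hard stop: detected within 3 frames."""
        n = 300
        stop_idx = 200
        v = np.zeros(n)
        v[:stop_idx] = np.linspace(0, 10, stop_idx)
        cols = 30 + np.cumsum(v) / self.rate / 25e-6
        kin = self._kin_from_cols(cols, smoothing=1)
        events = nc.detect_motion_events(kin, v_threshold=7.0)
        assert abs(events.stop_time - stop_idx / self.rate) <= 3 / self.rate
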