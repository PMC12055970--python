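"""Projected-area estimator: binarisation, rest-reference subtraction,
pixel-count arithmetic at the 25 µm optical scale, and replicate statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import needlecav as nc
from needlecav.core import VideoSequence
from needlecav.synthetic import (
    BubbleEvent,
    IntensityModel,
    SyntheticScene,
    static_motion,
)

BG, FG = 220, 30


def frame_with(mask: np.ndarray) -> np.ndarray:
    f = np.full(mask.shape, BG, dtype=np.uint8)
    f[mask] = FG
    return f


class TestBinarize:
    def test_bimodal_frame_threshold_separates_levels(self):
        mask = np.zeros((64, 64), bool)
        mask[10:30, 5:25] = True
        bin_mask, thr = nc.binarize_frame(frame_with(mask))
        assert FG <= thr < BG
        assert np.array_equal(bin_mask, mask)

    def test_fixed_level_on_background_only(self):
        f = np.full((32, 32), BG, np.uint8)
        m, thr = nc.binarize_frame(f, method="fixed", level=128)
        assert thr == 128 and m.sum() == 0

    def test_constant_frame_otsu_raises_with_guidance(self):
        f = np.full((16, 16), 100, np.uint8)
        with pytest.raises(ValueError, match="fixed"):
            nc.binarize_frame(f)

    def test_rest_frame_identity_count(self):
        mask = np.zeros((64, 64), bool)
        mask[:, 10:20] = True
        ref = nc.build_rest_reference([frame_with(mask)])
        m, _ = nc.binarize_frame(frame_with(mask), method="fixed", level=ref.threshold)
        assert m.sum() == ref.rest_dark_count


class TestRestReference:
    def test_single_noiseless_frame_equals_its_binarisation(self):
        mask = np.zeros((40, 40), bool)
        mask[5:25, 8:14] = True
        ref = nc.build_rest_reference([frame_with(mask)])
        assert np.array_equal(ref.rest_mask, mask)

    def test_majority_vote_removes_salt_noise(self):
        mask = np.zeros((60, 60), bool)
        mask[:, 20:32] = True
        clean = frame_with(mask)
        rng = np.random.default_rng(0)
        noisy = [
            np.clip(clean + rng.normal(0, 5, clean.shape), 0, 255).astype(np.uint8)
            for _ in range(5)
        ]
        ref = nc.build_rest_reference(noisy)
        assert np.array_equal(ref.rest_mask, mask)

    def test_rest_count_matches_generator_silhouette(self):
        scene = SyntheticScene(
            needle_geometry="side_cut",
            motion_profile=static_motion(),
            duration_s=3e-5,
            time_start_s=0.0,
            intensity=IntensityModel(noise_sd=0.0),
        )
        video, truth = nc.generate_video(scene)
        # mid-level threshold marks exactly the pixels with > 1/2 coverage
        ref = nc.build_rest_reference([video.frames[0]], method="fixed", level=120)
        assert ref.rest_dark_count == truth.needle_pixel_count[0]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            nc.build_rest_reference([])


class TestAreaSeries:
    def test_5600_excess_pixels_read_3p5_mm2(self):
        """5600 x (0.025 mm)^2 = 3.5 mm², the printed side-cut maximum."""
        h, w = 288, 384
        needle = np.zeros((h, w), bool)
        needle[:, 180:204] = True
        rest = frame_with(needle)
        test = rest.copy()
        test[100:170, 250:330] = FG  # 70 x 80 = 5600 extra dark pixels
        ref = nc.build_rest_reference([rest])
        video = VideoSequence(
            np.stack([test]), frame_rate=100_000, pixel_pitch_um=25.0
        )
        series = nc.bubble_area_series(video, ref)
        assert series.areas[0] == pytest.approx(3.5, abs=1e-12)

    def test_rest_identical_frame_reads_exactly_zero(self):
        mask = np.zeros((64, 64), bool)
        mask[:, 30:40] = True
        rest = frame_with(mask)
        ref = nc.build_rest_reference([rest])
        video = VideoSequence(np.stack([rest]), 100_000, 25.0)
        assert nc.bubble_area_series(video, ref).areas[0] == 0.0

    def test_shape_mismatch_rejected(self):
        ref = nc.build_rest_reference([np.full((32, 32), BG, np.uint8)],
                                      method="fixed", level=128)
        video = VideoSequence(np.full((1, 16, 16), BG, np.uint8), 100_000, 25.0)
        with pytest.raises(ValueError, match="mismatch"):
            nc.bubble_area_series(video, ref)

    def test_negative_differences_clamped_and_logged(self):
        mask = np.zeros((64, 64), bool)
        mask[:, 30:40] = True
        ref = nc.build_rest_reference([frame_with(mask)])
        video = VideoSequence(
            np.full((3, 64, 64), BG, np.uint8), 100_000, 25.0
        )  # needle vanished: fewer dark pixels than at rest
        series = nc.bubble_area_series(video, ref)
        assert np.all(series.areas == 0.0)
        assert series.n_clamped == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_rasterised_truth_within_two_pixels(self, seed):
        """Noiseless randomised scenes: estimate equals the pixel-count truth
        to within 2 pixel-areas per event (rasterisation tolerance)."""
        rng = np.random.default_rng(seed)
        events = []
        for _ in range(3):
            a, b = rng.uniform(0.1, 0.35, 2)
            cy = rng.uniform(1.0, 8.5)
            cz = rng.uniform(0.8, 2.2)  # clear of the silhouette
            t0 = rng.uniform(0, 1e-4)
            events.append(BubbleEvent((cy, cz), (a, b), t0, t0 + rng.uniform(5e-5, 2e-4)))
        scene = SyntheticScene(
            needle_geometry="side_cut",
            motion_profile=static_motion(),
            bubble_events=events,
            duration_s=3e-4,
            time_start_s=0.0,
            intensity=IntensityModel(noise_sd=0.0),
            seed=seed,
        )
        video, truth = nc.generate_video(scene)
        # mid-level threshold isolates rasterisation from threshold placement
        ref = nc.build_rest_reference([video.frames[0]], method="fixed", level=120)
        series = nc.bubble_area_series(video, ref)
        err_px = np.abs(series.areas - truth.rasterized_areas) / video.pixel_area_mm2
        assert err_px.max() <= 2 * len(events)

    def test_noisy_scene_mean_error_stays_small(self):
        """Under the default noise SD the per-frame estimate fluctuates by
        boundary-pixel flips, but the mean over the event lifetime stays
        within a few pixel-areas of the truth."""
        ev = BubbleEvent((6.513, 2.022), (0.2, 0.2), 5e-5, 2.05e-4)
        scene = SyntheticScene(
            needle_geometry="side_cut",
            motion_profile=static_motion(),
            bubble_events=[ev],
            duration_s=3e-4,
            time_start_s=0.0,
            seed=3,
        )
        video, truth = nc.generate_video(scene)
        ref = nc.build_rest_reference([video.frames[k] for k in range(5)])
        series = nc.bubble_area_series(video, ref)
        alive = truth.rasterized_areas > 0
        mean_err_px = np.abs(
            (series.areas[alive] - truth.rasterized_areas[alive]).mean()
        ) / video.pixel_area_mm2
        assert mean_err_px <= 3.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_adding_dark_pixels_never_decreases_area(self, seed):
        rng = np.random.default_rng(seed)
        base = (rng.random((24, 24)) < 0.2)
        extra = base | (rng.random((24, 24)) < 0.1)
        ref = nc.build_rest_reference(
            [np.full((24, 24), BG, np.uint8)], method="fixed", level=128
        )
        a1 = nc.bubble_area_series(
            VideoSequence(np.stack([frame_with(base)]), 100_000, 25.0), ref
        ).areas[0]
        a2 = nc.bubble_area_series(
            VideoSequence(np.stack([frame_with(extra)]), 100_000, 25.0), ref
        ).areas[0]
        assert a2 >= a1

    def test_doubling_pitch_quadruples_area(self):
        mask = np.zeros((32, 32), bool)
        mask[4:10, 4:10] = True
        ref = nc.build_rest_reference(
            [np.full((32, 32), BG, np.uint8)], method="fixed", level=128
        )
        f = np.stack([frame_with(mask)])
        a25 = nc.bubble_area_series(VideoSequence(f, 100_000, 25.0), ref).areas[0]
        a50 = nc.bubble_area_series(VideoSequence(f, 100_000, 50.0), ref).areas[0]
        assert a50 == pytest.approx(4 * a25)


class TestSummary:
    def test_all_zero_series(self):
        s = nc.AreaSeries(times=np.arange(5) / 1e5, areas=np.zeros(5))
        summ = nc.summarize_area(s)
        assert summ.max_area == 0.0 and summ.duration == 0.0

    @pytest.mark.parametrize("n_alive,expected_ms", [(25, 0.25), (84, 0.84)])
    def test_duration_counts_frames_above_threshold(self, n_alive, expected_ms):
        n = 120
        areas = np.zeros(n)
        areas[10 : 10 + n_alive] = 0.5
        s = nc.AreaSeries(times=np.arange(n) / 1e5, areas=areas)
        assert nc.summarize_area(s).duration == pytest.approx(expected_ms * 1e-3)


class TestEnsemble:
    def _series(self, values):
        t = np.arange(len(values)) / 1e5
        return nc.AreaSeries(times=t, areas=np.asarray(values, float))

    def test_identical_replicates_have_zero_sd(self):
        ens = nc.ReplicateEnsemble([self._series([1, 2, 3])] * 9)
        _, mean, sd = nc.aggregate_replicates(ens)
        np.testing.assert_allclose(mean, [1, 2, 3])
        np.testing.assert_allclose(sd, 0.0)

    def test_sample_sd_uses_n_minus_one(self):
        ens = nc.ReplicateEnsemble([self._series([0.0]), self._series([2.0])])
        _, mean, sd = nc.aggregate_replicates(ens)
        assert mean[0] == pytest.approx(1.0)
        assert sd[0] == pytest.approx(np.sqrt(2.0))

    def test_nine_replicates_from_three_devices(self):
        series = [self._series([0.1 * i, 0.2 * i]) for i in range(9)]
        ens = nc.ReplicateEnsemble(
            series,
            device_ids=[f"d{i//3}" for i in range(9)],
            replicate_ids=[f"r{i%3}" for i in range(9)],
        )
        t, mean, sd = nc.aggregate_replicates(ens)
        assert mean.shape == (2,) and np.all(sd >= 0)

    def test_mismatched_grids_rejected(self):
        a = self._series([1, 2, 3])
        b = nc.AreaSeries(times=np.arange(3) / 2e5, areas=np.zeros(3))
        with pytest.raises(ValueError, match="common time grid"):
            nc.ReplicateEnsemble([a, b])
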