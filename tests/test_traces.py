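"""Fold-enrichment traces, peak alignment, and cohort statistics."""

import numpy as np
import pytest

from conftest import noiseless, small_movie_config
from repliphase.segment import LabelVolume, segment_frame
from repliphase.simulate import simulate_mitosis_movie
from repliphase.stack import ImageStack
from repliphase.tracking import NucleusTrack, build_tracks
from repliphase.traces import (
    EnrichmentTrace,
    align_on_peak,
    cohort_summary,
    estimate_background,
    fold_enrichment,
    measure_track_intensities,
    quantify_movie,
)


def _trace(fold_values, track_id=0):
    f = np.asarray(fold_values, dtype=float)
    return EnrichmentTrace(track_id=track_id, frames=list(range(len(f))),
                           time=np.arange(len(f), dtype=float),
                           fold={1: f}, mean_in={1: f},
                           background={1: np.ones_like(f)})


class TestMeasureIntensities:
    def _uniform_stack_and_labels(self, value=7.0):
        data = np.full((3, 2, 4, 8, 8), value)
        stack = ImageStack(data, voxel_size=(1, 1, 1), frame_interval=1.0)
        lab = np.zeros((4, 8, 8), dtype=np.int32)
        lab[1:3, 2:5, 2:5] = 1
        labels = [LabelVolume(lab, (1, 1, 1))] * 3
        tr = NucleusTrack(track_id=0)
        for t in range(3):
            tr.append(t, np.array([2.0, 3.0, 3.0]), 1)
        return stack, labels, [tr]

    def test_uniform_channel_mean(self):
        stack, labels, tracks = self._uniform_stack_and_labels(7.0)
        measure_track_intensities(stack, tracks, labels)
        assert tracks[0].intensities[0] == [7.0] * 3
        assert tracks[0].intensities[1] == [7.0] * 3

    def test_channels_measured_independently(self):
        stack, labels, tracks = self._uniform_stack_and_labels()
        stack.data[:, 1] *= 3
        measure_track_intensities(stack, tracks, labels)
        assert tracks[0].intensities[0] == [7.0] * 3
        assert tracks[0].intensities[1] == [21.0] * 3

    def test_missing_label_raises(self):
        stack, labels, tracks = self._uniform_stack_and_labels()
        tracks[0].labels[1] = 9
        with pytest.raises(ValueError):
            measure_track_intensities(stack, tracks, labels)

    def test_noise_free_movie_means_match_truth(self):
        cfg = small_movie_config(noise=noiseless(), psf_sigma=(0, 0, 0), seed=8,
                                 phase_schedule=[("telophase", 30.0)],
                                 enrichment_profile={"telophase": 2.0})
        stack, truth = simulate_mitosis_movie(cfg)
        gfp = stack.frame(0, 1)
        for nid in (1, 2):
            sel = truth.masks[0] == nid
            assert gfp[sel].mean() == pytest.approx(2.0 * truth.background)


class TestBackground:
    def test_uniform_outside_value(self):
        vol = np.full((6, 10, 10), 3.5)
        mask = np.zeros_like(vol, dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        vol[mask] = 99
        assert estimate_background(vol, mask) == 3.5

    def test_median_matches_sort_oracle(self, rng):
        from scipy.ndimage import binary_dilation

        vol = rng.random((6, 12, 12)) * 10
        vol[0, 0, 0] = 1e6  # impulse outlier: median shrugs it off
        mask = np.zeros_like(vol, dtype=bool)
        mask[2:4, 4:8, 4:8] = True
        dilated = binary_dilation(mask, iterations=2)
        expected = np.sort(vol[~dilated].ravel())
        n = len(expected)
        oracle = (expected[n // 2] if n % 2 else
                  0.5 * (expected[n // 2 - 1] + expected[n // 2]))
        assert estimate_background(vol, mask) == oracle

    def test_empty_mask_whole_volume_median(self, rng):
        vol = rng.random((4, 6, 6))
        assert estimate_background(vol, np.zeros_like(vol, bool)) == np.median(vol)

    def test_saturated_mask_rejected(self):
        vol = np.ones((4, 4, 4))
        with pytest.raises(ValueError):
            estimate_background(vol, np.ones_like(vol, bool))


class TestFoldEnrichment:
    def _track_with_means(self, means):
        tr = NucleusTrack(track_id=0)
        for t in range(len(means)):
            tr.append(t, np.zeros(3), 1)
        tr.intensities = {0: list(means)}
        return tr

    def test_equal_mean_and_background_gives_unity(self):
        tr = self._track_with_means([5.0, 5.0])
        trace = fold_enrichment(tr, {0: np.array([5.0, 5.0])})
        assert np.allclose(trace.fold[0], 1.0)

    def test_global_rescale_invariance(self):
        tr1 = self._track_with_means([4.0, 8.0])
        tr2 = self._track_with_means([12.0, 24.0])
        f1 = fold_enrichment(tr1, {0: np.array([2.0, 2.0])}).fold[0]
        f2 = fold_enrichment(tr2, {0: np.array([6.0, 6.0])}).fold[0]
        assert np.allclose(f1, f2)

    def test_zero_background_rejected(self):
        tr = self._track_with_means([1.0, 1.0])
        with pytest.raises(ValueError):
            fold_enrichment(tr, {0: np.array([1.0, 0.0])})

    def test_noise_free_recovery_within_psf_tolerance(self):
        """Full measurement on a blurred, noise-free movie recovers the
        configured factor within the PSF edge tolerance."""
        cfg = small_movie_config(noise=noiseless(), seed=9,
                                 phase_schedule=[("late_telophase", 30.0)],
                                 enrichment_profile={"late_telophase": 3.0})
        stack, truth = simulate_mitosis_movie(cfg)
        labels = [segment_frame(stack.frame(t, 0), voxel_size=stack.voxel_size,
                                block_size=(9, 41, 41), offset=120, min_size=80)
                  for t in range(stack.n_frames)]
        tracks = build_tracks(labels, max_disp=2.0)
        measure_track_intensities(stack, tracks, labels)
        bg = {c: np.array([estimate_background(stack.frame(t, c),
                                               labels[t].labels > 0)
                           for t in range(stack.n_frames)])
              for c in range(2)}
        for tr in tracks:
            trace = fold_enrichment(tr, bg)
            assert trace.fold[1][0] == pytest.approx(3.0, rel=0.05)


class TestAlignment:
    def test_triangle_peak_at_apex(self):
        t = _trace([1, 2, 3, 2, 1])
        offsets, matrix = align_on_peak([t], smooth_window=1)
        assert t.peak_index == 2
        assert matrix[0, offsets == 0] == 3

    def test_tie_breaks_to_earliest(self):
        t = _trace([1, 3, 1, 3, 1])
        align_on_peak([t], smooth_window=1)
        assert t.peak_index == 1

    def test_flat_trace_warns(self):
        t = _trace([2, 2, 2, 2])
        with pytest.warns(UserWarning):
            align_on_peak([t], smooth_window=1)
        assert t.peak_index == 0

    def test_shift_equivariance(self):
        base = [1, 1, 2, 5, 2, 1, 1, 1, 1]
        t1 = _trace(base)
        t2 = _trace([1, 1] + base[:-2])  # delayed by 2 frames
        align_on_peak([t1], smooth_window=3)
        align_on_peak([t2], smooth_window=3)
        assert t2.peak_index == t1.peak_index + 2

    def test_noisy_peak_recovered_within_one_frame(self, rng):
        """SNR ≥ 5 around a known peak frame: smoothing localizes it."""
        true_peak = 12
        x = np.arange(25)
        clean = 1 + 2.0 * np.exp(-0.5 * ((x - true_peak) / 3.5) ** 2)
        for _ in range(20):
            noisy = clean + rng.normal(0, 0.4 / 5, size=x.size)
            t = _trace(noisy)
            align_on_peak([t], smooth_window=3)
            assert abs(t.peak_index - true_peak) <= 1


class TestCohortSummary:
    def test_single_trace(self):
        t = _trace([1, 2, 3, 2])
        offsets, matrix = align_on_peak([t], smooth_window=1)
        s = cohort_summary(offsets, matrix)
        assert np.allclose(s.mean, [1, 2, 3, 2])
        assert np.all(s.sd == 0)
        assert s.n.tolist() == [1, 1, 1, 1]

    def test_maxima_statistics_sample_sd(self):
        """Maxima {2, 4}: mean 3, sample SD (n−1 denominator) = √2."""
        ts = [_trace([1, 2, 1]), _trace([1, 4, 1], track_id=1)]
        offsets, matrix = align_on_peak(ts, smooth_window=1)
        s = cohort_summary(offsets, matrix)
        assert s.max_mean == pytest.approx(3.0)
        assert s.max_sd == pytest.approx(np.sqrt(2.0))


class TestEndToEndRecovery:
    def test_null_factor_recovered(self):
        from repliphase.simulate import PHASES

        cfg = small_movie_config(
            seed=10, enrichment_profile={p: 1.0 for p in PHASES})
        stack, _ = simulate_mitosis_movie(cfg)
        _, summary = quantify_movie(
            stack, max_disp=4.0,
            segment_kwargs={"block_size": (9, 41, 41), "offset": 120,
                            "min_size": 80})
        assert summary.max_mean == pytest.approx(1.0, abs=0.1)
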