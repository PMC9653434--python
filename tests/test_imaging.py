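"""Two-photon pipeline tests against synthetic ground truth and hand oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from obfeedback import imaging, synth
from obfeedback.errors import (
    BaselineError,
    InvalidParameterError,
    PairingError,
    RoiError,
)
from conftest import make_movie


class TestFlagZFrames:
    def test_self_similar_frames_all_kept(self, textured_frame):
        movie = make_movie(np.stack([textured_frame] * 6))
        out = imaging.flag_z_frames(movie)
        assert out.kept_frames.all()

    def test_injected_noise_frames_exactly_flagged(self, corrupted_movie):
        movie, _, truth = corrupted_movie
        out = imaging.flag_z_frames(movie)
        np.testing.assert_array_equal(
            np.nonzero(~out.kept_frames)[0], truth.out_of_plane_frames
        )

    def test_unattainable_threshold_flags_noisy_frames(self, textured_frame):
        rng = np.random.default_rng(3)
        frames = np.stack([textured_frame + rng.normal(0, 1, textured_frame.shape)
                           for _ in range(6)])
        out = imaging.flag_z_frames(make_movie(frames), r_threshold=1.0)
        assert not out.kept_frames.any()

    def test_constant_frame_flagged_with_undefined_correlation(self, textured_frame):
        frames = np.stack([textured_frame] * 5 + [np.full_like(textured_frame, 5.0)])
        out = imaging.flag_z_frames(make_movie(frames))
        assert not out.kept_frames[-1]
        assert out.kept_frames[:-1].all()

    def test_permutation_covariance(self, corrupted_movie):
        movie, _, _ = corrupted_movie
        perm = np.random.default_rng(5).permutation(movie.n_frames)
        flags = imaging.flag_z_frames(movie).kept_frames
        permuted = dataclasses.replace(movie, frames=movie.frames[perm],
                                       kept_frames=np.ones(movie.n_frames, bool))
        flags_perm = imaging.flag_z_frames(permuted).kept_frames
        np.testing.assert_array_equal(flags_perm, flags[perm])

    def test_too_few_frames_rejected(self, textured_frame):
        with pytest.raises(InvalidParameterError):
            imaging.flag_z_frames(make_movie(textured_frame[None]))


class TestMotionCorrection:
    def test_aligned_movie_zero_shifts(self, small_movie):
        movie, _, _ = small_movie
        _, shifts = imaging.correct_lateral_motion(movie)
        assert np.allclose(shifts, 0.0)

    def test_injected_drift_recovered(self, corrupted_movie):
        movie, _, truth = corrupted_movie
        qc = imaging.flag_z_frames(movie)
        _, shifts = imaging.correct_lateral_motion(qc)
        kept = qc.kept_frames
        drifted = (truth.injected_shifts != 0).any(axis=1)
        # estimated corrections are defined up to the reference's global
        # offset; the drift is their difference between the two segments
        correction_drift = (
            shifts[kept & drifted].mean(axis=0) - shifts[kept & ~drifted].mean(axis=0)
        )
        assert np.all(np.abs(correction_drift + np.array([3, -2])) <= 0.5)

    def test_single_frame_identity(self, textured_frame):
        movie, shifts = imaging.correct_lateral_motion(make_movie(textured_frame[None]))
        np.testing.assert_array_equal(movie.frames[0], textured_frame)
        assert shifts.shape == (1, 2)

    def test_excessive_shift_flags_frame(self, textured_frame):
        frames = np.stack([textured_frame] * 8)
        frames[4] = np.roll(textured_frame, (10, 10), axis=(0, 1))  # > 10% of 32 px
        out, shifts = imaging.correct_lateral_motion(make_movie(frames))
        assert not out.kept_frames[4]
        assert np.allclose(shifts[4], 0.0)


class TestPcaReconstruct:
    @pytest.mark.parametrize("rank,k", [(1, 1), (5, 10)])
    def test_low_rank_movies_recovered_exactly(self, rank, k):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(40, rank))
        maps = rng.normal(size=(rank, 24 * 24))
        data = (scores @ maps).reshape(40, 24, 24)
        movie = make_movie(data - data.min() + 10.0)
        recon = imaging.pca_reconstruct(movie, n_components=k)
        assert np.abs(recon.frames - movie.frames).max() < 1e-8

    def test_idempotent(self, small_movie):
        movie, _, _ = small_movie
        once = imaging.pca_reconstruct(movie, n_components=10)
        twice = imaging.pca_reconstruct(once, n_components=10)
        assert np.abs(twice.frames - once.frames).max() < 1e-8

    def test_residual_below_noise_energy(self, small_movie):
        movie, _, truth = small_movie
        recon = imaging.pca_reconstruct(movie, n_components=10)
        residual = movie.frames - recon.frames
        noise_energy = truth.noise_sigma**2 * movie.frames.size
        assert (residual**2).sum() < noise_energy

    def test_component_count_validated(self, textured_frame):
        movie = make_movie(np.stack([textured_frame] * 5))
        with pytest.raises(InvalidParameterError):
            imaging.pca_reconstruct(movie, n_components=0)
        with pytest.raises(InvalidParameterError):
            imaging.pca_reconstruct(movie, n_components=5)


class TestRefineRois:
    def test_exact_cell_cover_unchanged(self, small_movie):
        movie, rois, _ = small_movie
        refined = imaging.refine_rois(movie, rois)
        np.testing.assert_array_equal(refined.masks, rois.masks)
        assert all(v == "refined" for v in refined.provenance.values())

    def test_overwide_roi_sheds_rim_pixels(self, small_movie):
        movie, rois, _ = small_movie
        fat = np.zeros_like(rois.masks)
        for lab in rois.labels:
            fat[ndimage.binary_dilation(rois.masks == lab, iterations=2)] = lab
        refined = imaging.refine_rois(movie, imaging.RoiSet(masks=fat))
        for lab in rois.labels:
            rim = (fat == lab) & (rois.masks != lab)
            kept_rim = ((refined.masks == lab) & rim).sum()
            assert kept_rim <= 0.2 * rim.sum()

    def test_pure_noise_roi_keeps_original_mask(self):
        rng = np.random.default_rng(1)
        movie = make_movie(rng.normal(100, 3, (100, 20, 20)))
        mask = np.zeros((20, 20), int)
        mask[5:10, 5:10] = 1
        refined = imaging.refine_rois(movie, imaging.RoiSet(masks=mask))
        np.testing.assert_array_equal(refined.masks, mask)
        assert refined.provenance[1] == "manual"

    def test_tiny_roi_rejected(self, small_movie):
        movie, _, _ = small_movie
        mask = np.zeros(movie.shape[1:], int)
        mask[0, :3] = 1
        with pytest.raises(InvalidParameterError):
            imaging.refine_rois(movie, imaging.RoiSet(masks=mask))


class TestExtractTraces:
    def test_uniform_movie(self):
        movie = make_movie(np.full((10, 8, 8), 7.0))
        mask = np.zeros((8, 8), int)
        mask[2:5, 2:5] = 1
        traces = imaging.extract_traces(movie, imaging.RoiSet(masks=mask))
        assert np.allclose(traces.traces, 7.0)

    def test_single_pixel_roi_equals_pixel_series(self, textured_frame):
        rng = np.random.default_rng(2)
        frames = np.stack([textured_frame + rng.normal(0, 1, textured_frame.shape)
                           for _ in range(12)])
        mask = np.zeros((32, 32), int)
        mask[4, 9] = 1
        traces = imaging.extract_traces(make_movie(frames), imaging.RoiSet(masks=mask))
        np.testing.assert_allclose(traces.traces[0], frames[:, 4, 9])

    def test_ground_truth_correlation(self, small_movie):
        movie, rois, truth = small_movie
        traces = imaging.extract_traces(movie, rois)
        for i in range(traces.n_cells):
            r = np.corrcoef(traces.traces[i], truth.clean_traces[i])[0, 1]
            assert r >= 0.8

    def test_not_kept_frames_interpolated(self):
        frames = np.full((6, 4, 4), 1.0) * np.arange(1, 7)[:, None, None]
        movie = make_movie(frames)
        movie.kept_frames[3] = False
        movie.frames[3] = 99.0  # corrupted frame value must not leak through
        mask = np.ones((4, 4), int)
        traces = imaging.extract_traces(movie, imaging.RoiSet(masks=mask))
        assert traces.traces[0, 3] == pytest.approx(4.0)  # midpoint of 3 and 5

    def test_empty_roi_errors(self):
        movie = make_movie(np.zeros((5, 4, 4)) + 1.0)
        with pytest.raises(RoiError):
            imaging.extract_traces(movie, imaging.RoiSet(masks=np.zeros((4, 4), int)))


class TestSmoothing:
    def test_window_one_is_identity(self):
        ts = imaging.TraceSet(traces=np.arange(10.0)[None], frame_rate=15.0)
        out = imaging.smooth_traces(ts, window=1)
        np.testing.assert_array_equal(out.traces, ts.traces)

    def test_impulse_becomes_box(self):
        x = np.zeros(11)
        x[5] = 5.0
        ts = imaging.TraceSet(traces=x[None], frame_rate=15.0)
        out = imaging.smooth_traces(ts, window=5)
        np.testing.assert_allclose(out.traces[0, 3:8], 1.0)
        assert out.traces[0, 0] == 0.0

    def test_constant_unchanged_including_edges(self):
        ts = imaging.TraceSet(traces=np.full((1, 9), 3.3), frame_rate=15.0)
        out = imaging.smooth_traces(ts, window=5)
        np.testing.assert_allclose(out.traces, 3.3)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_zero_window_rejected(self, window):
        ts = imaging.TraceSet(traces=np.zeros((1, 9)), frame_rate=15.0)
        with pytest.raises(InvalidParameterError):
            imaging.smooth_traces(ts, window=window)


class TestDff:
    def test_constant_trace_all_zero(self):
        assert np.allclose(imaging.compute_dff(np.full(10, 4.0), (0, 5)), 0.0)

    def test_arithmetic(self):
        trace = np.array([10.0, 10.0, 12.0])
        out = imaging.compute_dff(trace, (0, 2))
        assert out[2] == pytest.approx(0.2)

    def test_gain_invariance(self):
        rng = np.random.default_rng(4)
        trace = rng.uniform(5, 10, 50)
        np.testing.assert_allclose(
            imaging.compute_dff(trace, (0, 10)),
            imaging.compute_dff(2.0 * trace, (0, 10)),
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(BaselineError):
            imaging.compute_dff(np.array([-1.0, -1.0, 5.0]), (0, 2))


class TestZScore:
    def test_worked_example(self):
        stat = imaging.compute_zscore([2, 3, 2, 3], [1, 1, 1, 1])
        assert stat.z == pytest.approx(1.5 * np.sqrt(12), abs=1e-9)  # = 5.196
        assert stat.mu_resp == 2.5
        assert stat.sigma_baseline == 0.0
        assert stat.n == 4

    def test_identical_windows_give_zero(self):
        stat = imaging.compute_zscore([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat.z == 0.0
        assert stat.label == "nonresponsive"

    def test_negative_radicand_reports_nan_with_pooled_fallback(self):
        stat = imaging.compute_zscore([5.0, 5.1, 4.9, 5.0], [1.0, 3.0, 2.0, 1.5])
        assert np.isnan(stat.z)
        assert np.isfinite(stat.z_pooled) and stat.z_pooled > 0

    @settings(max_examples=40, deadline=None)
    @given(
        shift=st.floats(-10, 10, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    def test_affine_invariance(self, shift, scale):
        resp = np.array([2.0, 3.0, 2.5, 3.5, 2.2])
        base = np.array([1.0, 1.2, 0.8, 1.1, 1.0])
        z0 = imaging.compute_zscore(resp, base).z
        z1 = imaging.compute_zscore(scale * resp + shift, scale * base + shift).z
        assert z1 == pytest.approx(z0, rel=1e-9)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(PairingError):
            imaging.compute_zscore([1.0, 2.0], [1.0, 2.0, 3.0])


class TestClassifyResponse:
    def test_identical_trials_nonresponsive_p_one(self):
        label, p = imaging.classify_response(np.ones(6), np.ones(6))
        assert label == "nonresponsive"
        assert p == 1.0

    def test_consistent_suppression_is_inhibited(self):
        base = np.zeros(6)
        resp = base + np.array([-1.1, -0.9, -1.0, -1.0, -1.05, -0.95])
        label, p = imaging.classify_response(resp, base, alpha=0.01)
        assert label == "inhibited"
        assert p < 0.01

    def test_zero_variance_nonzero_mean_degenerate(self):
        label, p = imaging.classify_response(np.full(5, 2.0), np.full(5, 1.0))
        assert p == 0.0
        assert label == "excited"

    def test_label_never_contradicts_mean_sign(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            resp = rng.normal(0, 1, 8)
            base = rng.normal(0, 1, 8)
            label, _ = imaging.classify_response(resp, base, alpha=0.05)
            if label == "excited":
                assert resp.mean() > base.mean()
            elif label == "inhibited":
                assert resp.mean() < base.mean()


class TestTrialWindows:
    def test_known_window_values(self, scaled_protocol):
        rate = 15.0
        n = int((scaled_protocol["onset_s"].max() + 10.0) * rate)
        times = (np.arange(n) + 0.5) / rate
        # trace equals 1 inside every response window, 0 elsewhere
        trace = np.zeros(n)
        for _, row in scaled_protocol.iterrows():
            open_s = row["shutter_open_s"]
            if np.isnan(open_s):
                open_s = row["onset_s"] + 1.0  # scaled stim length
            r0 = open_s + 0.05
            trace[(times >= r0) & (times < r0 + 1.0)] = 1.0
        ts = imaging.TraceSet(traces=trace[None], frame_rate=rate)
        base, resp = imaging.trial_window_means(ts, scaled_protocol)
        assert np.allclose(resp, 1.0)
        assert np.allclose(base, 0.0)

    def test_end_to_end_sensitivity_on_synthetic_movie(self, small_movie, scaled_protocol):
        """Ground-truth excited/inhibited cells are recovered by the paired test."""
        movie, rois, truth = small_movie
        qc = imaging.flag_z_frames(movie)
        reg, _ = imaging.correct_lateral_motion(qc)
        recon = imaging.pca_reconstruct(reg, n_components=10)
        refined = imaging.refine_rois(recon, rois)
        traces = imaging.smooth_traces(imaging.extract_traces(reg, refined), window=5)
        base, resp = imaging.trial_window_means(traces, scaled_protocol)
        light = scaled_protocol["stimulus"].str.contains("light").to_numpy()
        hits = 0
        active = [i for i, lab in enumerate(truth.cell_labels) if lab != "null"]
        for i in active:
            label, _ = imaging.classify_response(resp[i, light], base[i, light],
                                                 alpha=0.01)
            if label == truth.cell_labels[i]:
                hits += 1
        assert hits / len(active) >= 0.8
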