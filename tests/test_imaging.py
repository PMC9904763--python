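"""Contraction-assay quantification: thresholding, skeleton lengths, CT calls."""

import math

import numpy as np
import pytest
from skimage.draw import disk

from nocilab import imaging, skeleton as sk, synthetic as syn
from nocilab.errors import DegenerateSkeletonError, DiscardedTraceError, ValidationError

from conftest import small_scene


def _stack(frames, fps=8.0):
    return imaging.ImageStack(frames=np.asarray(frames), frame_interval=1.0 / fps)


class TestBinarize:
    def test_bright_rectangle_recovered(self):
        frame = np.full((50, 50), 10.0)
        frame[10:30, 5:40] = 200.0
        mask = imaging.binarize(frame)
        expected = np.zeros((50, 50), bool)
        expected[10:30, 5:40] = True
        assert np.array_equal(mask, expected)

    def test_flat_frame_flags_invalid(self):
        assert imaging.binarize(np.full((30, 30), 7.0)) is None

    def test_synthetic_larva_iou(self):
        spec = small_scene(0.0, seed=8, n_frames=2)
        frames, truth = syn.generate_larva_stack(spec)
        mask = imaging.binarize(frames[0])
        inter = (mask & truth.body_mask).sum()
        union = (mask | truth.body_mask).sum()
        assert inter / union >= 0.9


class TestSkeleton:
    def test_thin_bar_is_its_own_skeleton(self):
        img = np.zeros((7, 60), bool)
        img[3, 5:55] = True
        g = imaging.skeletonize(img)
        assert len(sk.endpoints(g)) == 2
        assert g.number_of_nodes() == 50

    def test_filled_disk_degenerates(self):
        img = np.zeros((64, 64), bool)
        rr, cc = disk((32, 32), 20)
        img[rr, cc] = True
        g = imaging.skeletonize(img)
        with pytest.raises(DegenerateSkeletonError):
            imaging.skeleton_length(g)

    def test_larva_masks_have_two_endpoints_after_pruning(self):
        """Property: pruned synthetic larva skeletons are simple open curves."""
        bad = 0
        for seed in range(100):
            spec = small_scene(0.0, seed=300 + seed, n_frames=2)
            frames, _ = syn.generate_larva_stack(spec)
            g = imaging.skeletonize(imaging.binarize(frames[0]))
            if len(sk.endpoints(g)) != 2:
                bad += 1
        assert bad == 0

    @pytest.mark.parametrize("n", [10, 50, 173])
    def test_horizontal_line_length_exact(self, n):
        img = np.zeros((5, n + 10), bool)
        img[2, 5 : 5 + n] = True
        assert imaging.skeleton_length(imaging.skeletonize(img)) == pytest.approx(n - 1)

    @pytest.mark.parametrize("n", [10, 50])
    def test_diagonal_line_length_exact(self, n):
        img = np.zeros((n + 10, n + 10), bool)
        for i in range(n):
            img[5 + i, 5 + i] = True
        assert imaging.skeleton_length(imaging.skeletonize(img)) == pytest.approx(
            (n - 1) * math.sqrt(2)
        )

    def test_length_close_to_analytic_spine(self):
        spec = small_scene(0.0, seed=17, n_frames=2)
        frames, truth = syn.generate_larva_stack(spec)
        g = imaging.skeletonize(imaging.binarize(frames[0]))
        rec = imaging.skeleton_length(g)
        assert abs(rec - truth.length_px[0]) / truth.length_px[0] <= 0.03

    def test_scale_equivariance(self):
        lengths = {}
        for L in (150.0, 300.0):
            spec = syn.LarvaSceneSpec(
                image_size=(420, 420), n_frames=2, frame_rate=8.0, spine_length=L, seed=21
            )
            frames, _ = syn.generate_larva_stack(spec)
            lengths[L] = imaging.skeleton_length(imaging.skeletonize(imaging.binarize(frames[0])))
        assert lengths[300.0] / lengths[150.0] == pytest.approx(2.0, rel=0.03)


class TestLengthTrace:
    def test_constant_scene_normalizes_to_one(self):
        frames, _ = syn.generate_larva_stack(small_scene(0.0, seed=30, n_frames=16))
        trace = imaging.length_trace(_stack(frames))
        assert not trace.discarded
        assert np.allclose(trace.normalized[trace.valid], 1.0, atol=0.02)

    def test_programmed_contraction_min_recovered(self):
        frames, _ = syn.generate_larva_stack(small_scene(0.35, seed=31))
        trace = imaging.length_trace(_stack(frames))
        assert np.nanmin(trace.normalized[trace.valid]) == pytest.approx(0.65, abs=0.02)

    def test_window_restricts_frames(self):
        frames, _ = syn.generate_larva_stack(small_scene(0.0, seed=32))
        trace = imaging.length_trace(_stack(frames), window_s=2.0)
        assert len(trace.times) == 17  # 2 s at 8 fps, inclusive of frame 0

    def test_blank_frame0_discards_trace(self):
        frames, _ = syn.generate_larva_stack(small_scene(0.0, seed=33, n_frames=10))
        frames = frames.copy()
        frames[0] = 0.0
        trace = imaging.length_trace(_stack(frames))
        assert trace.discarded
        assert "frame 0" in trace.discard_reason

    def test_jump_frames_flagged_invalid(self):
        frames, _ = syn.generate_larva_stack(small_scene(0.0, seed=34, n_frames=10))
        frames = frames.copy()
        frames[4] = 0.0  # unsegmentable frame
        trace = imaging.length_trace(_stack(frames))
        assert not trace.valid[4]


class TestCTThreshold:
    def test_control_cohort_formula(self):
        thr = imaging.compute_ct_threshold([0.1, 0.2, 0.3])
        assert thr.decrease_threshold == pytest.approx(0.35)
        assert thr.length_cutoff == pytest.approx(0.65)
        assert thr.source == "control_cohort"

    def test_identical_controls_zero_sd(self):
        thr = imaging.compute_ct_threshold([0.2, 0.2, 0.2])
        assert thr.decrease_threshold == pytest.approx(0.2)

    def test_default_is_thirty_percent_reduction(self):
        thr = imaging.compute_ct_threshold()
        assert thr.decrease_threshold == pytest.approx(0.30)
        assert thr.length_cutoff == pytest.approx(0.70)
        assert thr.source == "fixed_default"

    def test_out_of_range_controls_rejected(self):
        with pytest.raises(ValidationError):
            imaging.compute_ct_threshold([0.2, 1.5])


def _trace_from_normalized(norm):
    norm = np.asarray(norm, dtype=float)
    return imaging.LengthTrace(
        times=np.arange(len(norm), dtype=float),
        length_px=100 * norm,
        normalized=norm,
        valid=np.ones(len(norm), bool),
    )


class TestClassify:
    def test_crossing_cutoff_is_strong(self):
        res = imaging.classify_ct(_trace_from_normalized([1.0, 0.8, 0.65]), imaging.compute_ct_threshold())
        assert res.strong_ct and res.peak_decrease == pytest.approx(0.35)

    def test_shallow_contraction_is_not_strong(self):
        res = imaging.classify_ct(_trace_from_normalized([1.0, 0.9, 0.75]), imaging.compute_ct_threshold())
        assert not res.strong_ct

    def test_normalization_arithmetic(self):
        res = imaging.classify_ct(_trace_from_normalized([1.0, 0.9, 0.7, 0.8]), imaging.compute_ct_threshold())
        assert res.peak_decrease == pytest.approx(0.3)
        assert res.time_of_peak == pytest.approx(2.0)

    def test_discarded_trace_refused(self):
        t = imaging.LengthTrace(
            times=[0.0, 1.0],
            length_px=[np.nan, np.nan],
            normalized=[np.nan, np.nan],
            valid=[False, False],
            discarded=True,
            discard_reason="frame 0 invalid",
        )
        with pytest.raises(DiscardedTraceError, match="frame 0"):
            imaging.classify_ct(t, imaging.compute_ct_threshold())

    def test_monotone_in_threshold(self):
        trace = _trace_from_normalized([1.0, 0.72, 0.86])
        strong = [
            imaging.classify_ct(trace, imaging.CTThreshold(thr)).strong_ct
            for thr in (0.1, 0.25, 0.28, 0.3, 0.5)
        ]
        # once a larva stops being strong it never becomes strong again
        assert strong == sorted(strong, reverse=True)


class TestCohort:
    def test_half_strong_proportion_se(self):
        results = [
            imaging.LarvaCTResult(0.4, 1.0, True) if i < 15 else imaging.LarvaCTResult(0.1, 1.0, False)
            for i in range(30)
        ]
        traces = [_trace_from_normalized([1.0, 0.9]) for _ in range(30)]
        s = imaging.summarize_cohort(results, traces)
        assert s.pct_strong == pytest.approx(50.0)
        assert s.pct_strong_se == pytest.approx(9.1287, abs=1e-3)

    def test_zero_strong_zero_se(self):
        results = [imaging.LarvaCTResult(0.1, 1.0, False) for _ in range(30)]
        traces = [_trace_from_normalized([1.0, 0.9]) for _ in range(30)]
        s = imaging.summarize_cohort(results, traces)
        assert s.pct_strong == 0.0 and s.pct_strong_se == 0.0

    def test_mean_peak_sem(self):
        results = [imaging.LarvaCTResult(p, 1.0, True) for p in (0.2, 0.3, 0.4)]
        traces = [_trace_from_normalized([1.0, 1 - p]) for p in (0.2, 0.3, 0.4)]
        s = imaging.summarize_cohort(results, traces)
        assert s.mean_peak == pytest.approx(0.3)
        assert s.sem_peak == pytest.approx(0.0577, abs=1e-3)

    def test_heatmap_row_minima_match_peaks(self):
        peaks = (0.15, 0.4, 0.05)
        results = []
        traces = []
        for p in peaks:
            t = _trace_from_normalized([1.0, 1 - p / 2, 1 - p])
            traces.append(t)
            results.append(imaging.classify_ct(t, imaging.compute_ct_threshold()))
        s = imaging.summarize_cohort(results, traces)
        assert np.allclose(np.nanmin(s.heatmap, axis=1), [1 - p for p in peaks])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            imaging.summarize_cohort([], [])


class TestOpto:
    def test_constant_area_no_ct_call(self):
        spec = small_scene(0.0, seed=40, n_frames=25)  # ~3.1 s at 8 fps
        frames, _ = syn.generate_larva_stack(spec)
        trace, metrics = imaging.opto_analyze(_stack(frames), epochs=(1.0, 2.0, 0.0))
        pre = trace.times < 1.0
        assert trace.normalized[pre].mean() == pytest.approx(1.0)
        assert not metrics.ct_call

    def test_programmed_area_drop_recovered(self):
        # contraction shortens the body; area tracks the ground-truth area trace
        spec = syn.LarvaSceneSpec(
            n_frames=64,
            frame_rate=8.0,
            contraction_magnitude=0.4,
            contraction_onset=2.0,
            contraction_duration=5.0,
            seed=41,
        )
        frames, truth = syn.generate_larva_stack(spec)
        trace, metrics = imaging.opto_analyze(_stack(frames), epochs=(2.0, 5.0, 1.0))
        true_norm = truth.area_px / truth.area_px[(truth.times < 2.0)].mean()
        assert metrics.min_normalized_area == pytest.approx(true_norm.min(), abs=0.02)
        assert metrics.ct_call

    def test_short_stack_rejected(self):
        frames, _ = syn.generate_larva_stack(small_scene(0.0, seed=42, n_frames=10))
        with pytest.raises(ValidationError):
            imaging.opto_analyze(_stack(frames), epochs=(5.0, 10.0, 5.0))
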