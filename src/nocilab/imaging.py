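"""Cold-plate contraction (CT) assay and optogenetic area analysis.

The CT pipeline mirrors the classic image-based workflow: each grayscale
frame is thresholded, the largest foreground blob is skeletonized into a
single-pixel-wide line, and the tip-to-tip geodesic along that line is the
larva's length.  Lengths are normalized to the length at time 0 and the
peak fractional decrease within the first seconds of cold exposure is the
contraction magnitude.  A larva counts as a "strong CT" when its peak
decrease reaches the strong-CT threshold — by default a 30% reduction in
body length, i.e. a cutoff of 0.7 on the normalized-length scale; the
threshold can instead be derived from a control cohort as
mean peak decrease + 1.5 x sample SD.

The optogenetic analysis tracks total body area from above through
pre-stimulus / light / post-stimulus epochs and normalizes to the mean
pre-stimulus area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import remove_small_objects

from . import skeleton as sk
from .errors import DegenerateSkeletonError, DiscardedTraceError, ValidationError


@dataclass(frozen=True)
class ImageStack:
    """A time-ordered grayscale image stack."""

    frames: np.ndarray           # (n, H, W)
    frame_interval: float        # s
    pixel_size: float | None = None  # um/px

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 2:
            raise ValidationError("stack needs >= 2 frames of constant shape")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def binarize(
    frame: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    min_area: int = 30,
) -> np.ndarray | None:
    """Threshold one frame into a foreground mask.

    ``method`` is ``"otsu"`` (per-frame Otsu, default) or ``"fixed"`` with an
    explicit ``threshold``.  Objects smaller than ``min_area`` px are
    removed.  Returns ``None`` for an empty foreground (the frame is flagged
    invalid upstream rather than raising).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValidationError("frame must be 2-D")
    if method == "otsu":
        if np.ptp(frame) == 0:
            return None
        thr = threshold_otsu(frame)
    elif method == "fixed":
        if threshold is None:
            raise ValidationError("fixed method requires a threshold")
        thr = threshold
    else:
        raise ValidationError(f"unknown binarize method {method!r}")
    mask = frame > thr
    mask = remove_small_objects(mask, max_size=min_area)
    if not mask.any():
        return None
    return mask


def largest_component(mask: np.ndarray) -> np.ndarray:
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        raise ValidationError("mask is empty")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def skeletonize(mask: np.ndarray, method: str = "thin", prune: bool = True):
    """Skeletonize a mask into the shared single-pixel-wide skeleton graph.

    Takes the largest connected component, thins it, and prunes spur
    branches shorter than half the estimated body width (mask area divided
    by skeleton pixel count), which removes thinning artifacts that would
    otherwise create spurious endpoints.
    """
    mask = largest_component(np.asarray(mask, dtype=bool))
    skel = sk.thin_mask(mask, method=method)
    g = sk.skeleton_graph(skel)
    if g.number_of_nodes() == 0:
        raise DegenerateSkeletonError("thinning produced an empty skeleton")
    if prune and g.number_of_nodes() > 1:
        width_est = mask.sum() / max(g.number_of_nodes(), 1)
        g = sk.prune_spurs(g, min_length=width_est / 2.0)
    return g


def skeleton_length(graph, smooth: bool = True) -> float:
    """Tip-to-tip length: the maximum endpoint-pair geodesic of the skeleton.

    The path is chosen by the 1/sqrt(2) chamfer geodesic; by default its
    length is reported with staircase smoothing (exact on axis-aligned and
    diagonal lines, unbiased on oblique ones).  ``smooth=False`` returns the
    raw chamfer geodesic.
    """
    return sk.tip_to_tip(graph, smooth=smooth).length


@dataclass(frozen=True)
class LengthTrace:
    """Per-frame tip-to-tip larval length, raw and normalized to frame 0."""

    times: np.ndarray
    length_px: np.ndarray
    normalized: np.ndarray
    valid: np.ndarray
    discarded: bool = False
    discard_reason: str | None = None

    def __post_init__(self):
        for name in ("times", "length_px", "normalized"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))


def length_trace(
    stack: ImageStack,
    window_s: float = 5.0,
    binarize_method: str = "otsu",
    fixed_threshold: float | None = None,
    max_step: float = 0.2,
    max_invalid_frac: float = 0.2,
    median_filter: bool = False,
) -> LengthTrace:
    """Measure normalized larval length over the first ``window_s`` seconds.

    Frames that fail thresholding/skeletonization, or whose normalized
    length jumps by more than ``max_step`` from the previous valid frame,
    are flagged invalid; a trace with more than ``max_invalid_frac`` invalid
    frames (or an invalid frame 0) is marked discarded.
    """
    n = min(stack.n_frames, int(np.floor(window_s / stack.frame_interval)) + 1)
    times = stack.times[:n]
    lengths = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = binarize(stack.frames[i], method=binarize_method, threshold=fixed_threshold)
        if mask is None:
            continue
        try:
            g = skeletonize(mask)
            lengths[i] = skeleton_length(g)
            valid[i] = True
        except (DegenerateSkeletonError, ValidationError):
            continue
    if not valid[0]:
        return LengthTrace(
            times=times,
            length_px=lengths,
            normalized=np.full(n, np.nan),
            valid=valid,
            discarded=True,
            discard_reason="frame 0 invalid: cannot normalize",
        )
    normalized = lengths / lengths[0]
    if median_filter and n >= 3:
        from scipy.ndimage import median_filter as _medf

        smoothed = _medf(np.where(valid, normalized, np.nan), size=3, mode="nearest")
        normalized = np.where(np.isfinite(smoothed), smoothed, normalized)
    # jump rule against the previous valid frame
    last = normalized[0]
    for i in range(1, n):
        if not valid[i] or not np.isfinite(normalized[i]):
            valid[i] = False
            continue
        if abs(normalized[i] - last) > max_step:
            valid[i] = False
        else:
            last = normalized[i]
    discarded = (1.0 - valid.mean()) > max_invalid_frac
    return LengthTrace(
        times=times,
        length_px=lengths,
        normalized=normalized,
        valid=valid,
        discarded=discarded,
        discard_reason=(
            f"{(~valid).sum()}/{n} frames invalid (> {max_invalid_frac:.0%})" if discarded else None
        ),
    )


@dataclass(frozen=True)
class CTThreshold:
    """The strong-CT cutoff, on the peak-decrease and normalized-length scales."""

    decrease_threshold: float
    source: str = "fixed_default"  # or "control_cohort"
    control_n: int | None = None

    def __post_init__(self):
        if not 0.0 < self.decrease_threshold < 1.0:
            raise ValidationError("decrease_threshold must lie in (0, 1)")

    @property
    def length_cutoff(self) -> float:
        return 1.0 - self.decrease_threshold


DEFAULT_DECREASE_THRESHOLD = 0.30  # 30% body-length reduction, cutoff 0.7


def compute_ct_threshold(control_peak_decreases=None) -> CTThreshold:
    """Strong-CT threshold from a control cohort, or the fixed default.

    With controls: mean peak decrease + 1.5 x sample SD (n-1 denominator).
    Without controls: the study-wide default of a 30% reduction
    (normalized-length cutoff 0.7).
    """
    if control_peak_decreases is None:
        return CTThreshold(DEFAULT_DECREASE_THRESHOLD, source="fixed_default")
    vals = np.asarray(control_peak_decreases, dtype=float)
    if vals.size < 2:
        raise ValidationError("need >= 2 control peak decreases")
    if np.any((vals <= 0) | (vals >= 1)):
        raise ValidationError("control peak decreases must lie in (0, 1)")
    thr = float(vals.mean() + 1.5 * vals.std(ddof=1))
    return CTThreshold(thr, source="control_cohort", control_n=int(vals.size))


@dataclass(frozen=True)
class LarvaCTResult:
    peak_decrease: float
    time_of_peak: float
    strong_ct: bool


def classify_ct(trace: LengthTrace, threshold: CTThreshold) -> LarvaCTResult:
    """Peak fractional decrease over valid frames; strong CT if it reaches threshold."""
    if trace.discarded:
        raise DiscardedTraceError(f"trace was discarded: {trace.discard_reason}")
    dec = 1.0 - trace.normalized
    dec = np.where(trace.valid, dec, -np.inf)
    i = int(np.argmax(dec))
    peak = float(np.clip(dec[i], 0.0, 1.0))
    return LarvaCTResult(
        peak_decrease=peak,
        time_of_peak=float(trace.times[i]),
        strong_ct=bool(peak >= threshold.decrease_threshold),
    )


@dataclass(frozen=True)
class CohortCTSummary:
    n: int
    n_strong: int
    pct_strong: float
    pct_strong_se: float
    mean_peak: float
    sem_peak: float
    heatmap: np.ndarray = field(repr=False)  # larva x frame normalized length


def summarize_cohort(results, traces) -> CohortCTSummary:
    """Cohort-level % strong CT (± SE of the proportion), mean peak (± SEM), heatmap."""
    results = list(results)
    traces = list(traces)
    if not results:
        raise ValidationError("no non-discarded results to summarize")
    n = len(results)
    k = sum(r.strong_ct for r in results)
    p = k / n
    se = float(np.sqrt(p * (1 - p) / n)) * 100.0
    peaks = np.array([r.peak_decrease for r in results])
    sem = float(peaks.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    width = max(len(t.normalized) for t in traces)
    heat = np.full((len(traces), width), np.nan)
    for i, t in enumerate(traces):
        heat[i, : len(t.normalized)] = np.where(t.valid, t.normalized, np.nan)
    return CohortCTSummary(
        n=n,
        n_strong=int(k),
        pct_strong=100.0 * p,
        pct_strong_se=se,
        mean_peak=float(peaks.mean()),
        sem_peak=sem,
        heatmap=heat,
    )


@dataclass(frozen=True)
class AreaTrace:
    """Per-frame segmented larval area through pre/light/post epochs."""

    times: np.ndarray
    area_px: np.ndarray
    normalized: np.ndarray
    epochs: tuple[float, float, float]


@dataclass(frozen=True)
class OptoMetrics:
    min_normalized_area: float
    latency_s: float
    ct_call: bool


def opto_analyze(
    stack: ImageStack,
    epochs: tuple[float, float, float] = (5.0, 10.0, 5.0),
    area_cutoff: float = 0.8,
    binarize_method: str = "otsu",
    fixed_threshold: float | None = None,
) -> tuple[AreaTrace, OptoMetrics]:
    """Area-from-above optogenetic CT analysis.

    Segments every frame, normalizes area to the mean over the pre-stimulus
    epoch, and reports the minimum normalized area during the light epoch,
    the latency from light onset to that minimum, and a CT call when the
    minimum drops to ``area_cutoff`` or below.
    """
    pre_s, light_s, post_s = epochs
    if stack.n_frames * stack.frame_interval + 1e-9 < pre_s + light_s:
        raise ValidationError("stack shorter than pre + light epochs")
    times = stack.times
    areas = np.full(stack.n_frames, np.nan)
    for i in range(stack.n_frames):
        mask = binarize(stack.frames[i], method=binarize_method, threshold=fixed_threshold)
        if mask is not None:
            areas[i] = largest_component(mask).sum()
    pre = (times < pre_s) & np.isfinite(areas)
    if not pre.any():
        raise ValidationError("no segmentable frames in the pre-stimulus epoch")
    normalized = areas / areas[pre].mean()
    light = (times >= pre_s) & (times < pre_s + light_s) & np.isfinite(normalized)
    if not light.any():
        raise ValidationError("no segmentable frames in the light epoch")
    li = np.flatnonzero(light)
    j = li[int(np.argmin(normalized[li]))]
    mn = float(normalized[j])
    metrics = OptoMetrics(
        min_normalized_area=mn,
        latency_s=float(times[j] - pre_s),
        ct_call=bool(mn <= area_cutoff),
    )
    return AreaTrace(times=times, area_px=areas, normalized=normalized, epochs=epochs), metrics
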