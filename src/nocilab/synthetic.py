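"""Seeded synthetic-data generators with machine-readable ground truth.

Every input the pipeline consumes can be fabricated here: top-view clips of
a crawling larva with a programmed cold-evoked contraction (CT), cold-ramp
extracellular recordings with bursting during ramps and tonic firing at
holds, rasterized neuron arbors with known branch count and length, and
gentle-touch score tables.  Each generator takes an explicit seed and emits
a ground-truth record alongside the data, so downstream stages can be
tested without any external recordings.

The larval spine is built in arc-length parametrization: a heading angle
that varies slowly along the body is integrated into a smooth planar curve,
so the curve's true length equals the requested spine length *exactly*, and
a contraction to fraction ``1 - m`` of the body is simply the central
sub-curve of that arc length.  Body radius tapers elliptically at both tips
so that skeletonization recovers length all the way to the tips, as it does
on real larvae whose silhouette tapers at head and tail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.draw import disk as _disk
from skimage.draw import line as _line

from .errors import ValidationError

REFRACTORY_FLOOR_S = 2.5e-3  # physiological floor imposed on every generated ISI


# ---------------------------------------------------------------------------
# temperature protocols


@dataclass(frozen=True)
class TemperatureProtocol:
    """Piecewise-linear temperature program.

    ``segments`` is an ordered list of ``(duration_s, start_temp, end_temp)``;
    temperature is linearly interpolated within each segment and consecutive
    segments must be continuous.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if not self.segments:
            raise ValidationError("protocol needs at least one segment")
        prev_end = None
        for dur, t0, t1 in self.segments:
            if dur <= 0:
                raise ValidationError("segment durations must be > 0")
            for t in (t0, t1):
                if not 0.0 <= t <= 40.0:
                    raise ValidationError("temperatures must lie in [0, 40] degC")
            if prev_end is not None and abs(t0 - prev_end) > 1e-9:
                raise ValidationError("consecutive segments must be continuous in temperature")
            prev_end = t1

    @property
    def duration(self) -> float:
        return float(sum(s[0] for s in self.segments))

    @classmethod
    def ramp_and_hold(
        cls,
        room: float = 22.0,
        setpoints: tuple[float, ...] = (20.0, 15.0, 10.0),
        room_s: float = 30.0,
        ramp_rate: float = 0.5,
        hold_s: float = 60.0,
    ) -> "TemperatureProtocol":
        """Room hold followed by ramp-and-hold steps down through ``setpoints``."""
        segs = [(room_s, room, room)]
        cur = room
        for sp in setpoints:
            ramp_s = abs(cur - sp) / ramp_rate
            segs.append((ramp_s, cur, sp))
            segs.append((hold_s, sp, sp))
            cur = sp
        return cls(tuple(segs))


@dataclass(frozen=True)
class TemperatureTrace:
    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.temps, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("times and temps must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temps", v)

    @property
    def duration(self) -> float:
        return float(self.times[-1])


def generate_temperature_trace(protocol: TemperatureProtocol, dt: float) -> TemperatureTrace:
    """Sample a protocol every ``dt`` seconds; segment endpoints are hit exactly."""
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    times = np.arange(0.0, protocol.duration + dt / 2, dt)
    bounds = np.cumsum([0.0] + [s[0] for s in protocol.segments])
    temps = np.empty_like(times)
    for i, (dur, t0, t1) in enumerate(protocol.segments):
        lo, hi = bounds[i], bounds[i + 1]
        sel = (times >= lo - 1e-12) & (times <= hi + 1e-12)
        frac = np.clip((times[sel] - lo) / dur, 0.0, 1.0)
        temps[sel] = t0 + (t1 - t0) * frac
    return TemperatureTrace(times=times, temps=temps)


# ---------------------------------------------------------------------------
# larva scenes


@dataclass(frozen=True)
class LarvaSceneSpec:
    """Parameters for a synthetic top-view larva clip.

    The clip renders a worm-like body of ``spine_length`` px and width
    ``body_width`` px; during ``[contraction_onset, onset + duration]`` the
    body's arc length is scaled by ``1 - contraction_magnitude`` about the
    body midpoint, with a smooth 0.5-s onset/offset ramp so consecutive
    frames never jump.
    """

    image_size: tuple[int, int] = (300, 300)
    frame_rate: float = 30.0
    n_frames: int = 150
    spine_length: float = 200.0
    body_width: float = 12.0
    contraction_magnitude: float = 0.0
    contraction_onset: float = 1.0
    contraction_duration: float = 3.0
    recovery: bool = False
    ramp_s: float = 1.0
    background_level: float = 20.0
    foreground_level: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.contraction_magnitude < 0.9 + 1e-12:
            raise ValidationError("contraction_magnitude must lie in [0, 0.9]")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.spine_length <= 2 * self.body_width:
            raise ValidationError("spine_length must exceed twice body_width")
        h, w = self.image_size
        # spine must fit inside the image with margin >= body_width even fully curled
        if min(h, w) < self.spine_length / 2 + 4 * self.body_width:
            raise ValidationError(
                "image_size too small for spine_length: spine must fit with margin >= body_width"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LarvaGroundTruth:
    """Analytic per-frame truth co-generated with a larva clip."""

    times: np.ndarray
    length_px: np.ndarray          # true tip-to-tip arc length per frame
    normalized: np.ndarray         # length / length at frame 0
    peak_decrease: float           # max of 1 - normalized
    area_px: np.ndarray            # rendered (noise-free) foreground pixel count
    body_mask: np.ndarray = field(repr=False)  # frame-0 noise-free mask

    def to_json(self) -> str:
        d = {
            "times": self.times.tolist(),
            "length_px": self.length_px.tolist(),
            "normalized": self.normalized.tolist(),
            "peak_decrease": self.peak_decrease,
            "area_px": self.area_px.tolist(),
        }
        return json.dumps(d)


def _spine_curve(spec: LarvaSceneSpec, rng: np.random.Generator, ds: float = 0.5):
    """Arc-length-parametrized smooth spine that fits the image with margin.

    Returns (s, points) with points.shape == (len(s), 2) in (row, col)
    coordinates; total arc length equals spec.spine_length exactly by
    construction.
    """
    h, w = spec.image_size
    L = spec.spine_length
    s = np.arange(0.0, L + ds / 2, ds)
    margin = 2.0 * spec.body_width
    amp = 0.4  # gentle curvature: larvae on the plate are nearly straight
    for _ in range(60):
        theta0 = rng.uniform(0, 2 * np.pi)
        a1, a2 = rng.uniform(0.2, 1.0, size=2) * amp
        f1 = rng.uniform(0.5, 1.2)
        f2 = rng.uniform(1.5, 2.5)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        theta = theta0 + a1 * np.sin(2 * np.pi * f1 * s / L + ph1) + a2 * np.sin(
            2 * np.pi * f2 * s / L + ph2
        )
        # midpoint integration keeps per-step chord length == ds exactly
        mid = 0.5 * (theta[:-1] + theta[1:])
        dr = np.concatenate([[0.0], np.cumsum(ds * np.sin(mid))])
        dc = np.concatenate([[0.0], np.cumsum(ds * np.cos(mid))])
        pts = np.stack([dr, dc], axis=1)
        center = (pts.min(axis=0) + pts.max(axis=0)) / 2
        pts = pts - center + np.array([h / 2.0, w / 2.0])
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        if lo[0] >= margin and lo[1] >= margin and hi[0] <= h - margin and hi[1] <= w - margin:
            return s, pts
        amp *= 0.8
    raise ValidationError("could not fit spine in image; increase image_size")


def _contraction_profile(spec: LarvaSceneSpec, t: np.ndarray) -> np.ndarray:
    """Smooth fraction-of-maximal-contraction profile in [0, 1] per frame."""
    on, dur, ramp = spec.contraction_onset, spec.contraction_duration, spec.ramp_s
    rise = np.clip((t - on) / max(ramp, 1e-9), 0.0, 1.0)
    prof = 0.5 - 0.5 * np.cos(np.pi * rise)
    if spec.recovery:
        fall = np.clip((t - (on + dur)) / max(ramp, 1e-9), 0.0, 1.0)
        prof = prof * (0.5 + 0.5 * np.cos(np.pi * fall))
    return spec.contraction_magnitude * prof


def _radius_profile(arc: np.ndarray, r0: float, taper: float) -> np.ndarray:
    """Body radius along the spine: constant r0 with a pointed linear taper at
    both tips, so thinning recovers skeleton length all the way to the tips."""
    d = np.minimum(arc - arc[0], arc[-1] - arc)
    return r0 * np.clip(d / taper, 0.0, 1.0)


def _render_frame(spec, s, pts, frac, rng):
    """Render one frame; returns (image float32, noise-free mask, true length)."""
    h, w = spec.image_size
    L = spec.spine_length
    keep = L * (1.0 - frac)
    lo, hi = (L - keep) / 2.0, (L + keep) / 2.0
    sel = (s >= lo - 1e-9) & (s <= hi + 1e-9)
    sub = pts[sel]
    arc = s[sel]
    r0 = spec.body_width / 2.0
    radii = _radius_profile(arc, r0, taper=2.0 * spec.body_width)
    mask = np.zeros((h, w), dtype=bool)
    for (r, c), rad in zip(sub, radii):
        if rad < 0.5:
            rad = 0.5
        rr, cc = _disk((r, c), rad, shape=(h, w))
        mask[rr, cc] = True
    img = np.full((h, w), spec.background_level, dtype=np.float32)
    img[mask] = spec.foreground_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    return img, mask, keep


def generate_larva_stack(spec: LarvaSceneSpec) -> tuple[np.ndarray, LarvaGroundTruth]:
    """Render a larva clip with a programmed contraction.

    Returns ``(frames, truth)`` where ``frames`` has shape
    ``(n_frames, H, W)`` (float32 intensity) and ``truth`` carries the exact
    per-frame spine arc length, its normalization to frame 0, the programmed
    peak decrease actually reached, and the noise-free foreground area.
    """
    rng = np.random.default_rng(spec.seed)
    s, pts = _spine_curve(spec, rng)
    t = np.arange(spec.n_frames) / spec.frame_rate
    fracs = _contraction_profile(spec, t)
    noise_rng = np.random.default_rng(rng.integers(0, 2**31))
    frames = np.empty((spec.n_frames, *spec.image_size), dtype=np.float32)
    lengths = np.empty(spec.n_frames)
    areas = np.empty(spec.n_frames, dtype=np.int64)
    mask0 = None
    for i, frac in enumerate(fracs):
        img, mask, keep = _render_frame(spec, s, pts, frac, noise_rng)
        frames[i] = img
        lengths[i] = keep
        areas[i] = int(mask.sum())
        if i == 0:
            mask0 = mask
    normalized = lengths / lengths[0]
    truth = LarvaGroundTruth(
        times=t,
        length_px=lengths,
        normalized=normalized,
        peak_decrease=float(np.max(1.0 - normalized)),
        area_px=areas,
        body_mask=mask0,
    )
    return frames, truth


# ---------------------------------------------------------------------------
# spike recordings


@dataclass(frozen=True)
class SpikeGenSpec:
    """Parameters of the cold-ramp extracellular recording generator.

    Tonic firing follows ``baseline_rate + rate_gain * max(0, t_ref - T)``
    (rate rises as the bath cools below the reference temperature); while
    temperature is falling, burst events at ``ramp_burst_rate`` insert spike
    clusters whose intra-burst ISIs are drawn from
    ``intra_burst_isi_range`` (upper bound < 0.2 s, the burst criterion).
    """

    sampling_rate: float = 10_000.0
    baseline_rate: float = 0.5
    rate_gain: float = 0.4           # Hz per degC of cooling below t_ref
    t_ref: float = 22.0
    ramp_burst_rate: float = 0.5     # bursts/s while dT/dt < 0
    burst_size_range: tuple[int, int] = (3, 6)
    intra_burst_isi_range: tuple[float, float] = (0.01, 0.05)
    min_tonic_isi: float = 0.25      # renewal dead time for the tonic process
    template_amplitude: float = 1.0
    template_width_ms: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate < 1000:
            raise ValidationError("sampling_rate must be >= 1000 Hz")
        if min(self.baseline_rate, self.rate_gain, self.ramp_burst_rate) < 0:
            raise ValidationError("rates must be >= 0")
        if not self.intra_burst_isi_range[1] < 0.2:
            raise ValidationError("intra_burst_isi_range upper bound must be < 0.2 s")
        if self.intra_burst_isi_range[0] < REFRACTORY_FLOOR_S:
            raise ValidationError("intra-burst ISIs must respect the 2.5 ms refractory floor")
        if self.burst_size_range[0] < 2:
            raise ValidationError("bursts need >= 2 spikes")


@dataclass(frozen=True)
class SpikeGroundTruth:
    spike_times: np.ndarray
    burst_member: np.ndarray  # bool, True for spikes inserted by a burst event

    def to_json(self) -> str:
        return json.dumps(
            {
                "spike_times": self.spike_times.tolist(),
                "burst_member": self.burst_member.astype(int).tolist(),
            }
        )


def spike_template(spec: SpikeGenSpec) -> np.ndarray:
    """Biphasic waveform with its extremum at the center sample."""
    a = spec.template_width_ms * 1e-3 * spec.sampling_rate
    half = int(round(4 * a))
    x = np.arange(-half, half + 1, dtype=float)
    w = (1.0 - (x / a) ** 2) * np.exp(-(x**2) / (2 * a**2))
    return (spec.template_amplitude * w).astype(np.float64)


def _tonic_times(spec: SpikeGenSpec, temp: TemperatureTrace, rng) -> np.ndarray:
    """Dead-time-thinned inhomogeneous renewal process for tonic spikes."""
    duration = temp.duration
    rate = spec.baseline_rate + spec.rate_gain * np.maximum(0.0, spec.t_ref - temp.temps)
    rmax = float(rate.max())
    if rmax <= 0:
        return np.empty(0)
    times = []
    t = 0.0
    last = -np.inf
    while True:
        t += rng.exponential(1.0 / rmax)
        if t > duration:
            break
        r_t = np.interp(t, temp.times, rate)
        if rng.uniform() < r_t / rmax and t - last >= spec.min_tonic_isi:
            times.append(t)
            last = t
    return np.asarray(times)


def _burst_times(spec: SpikeGenSpec, temp: TemperatureTrace, rng) -> list[np.ndarray]:
    """Burst spike clusters seeded while temperature is falling."""
    if spec.ramp_burst_rate <= 0 or len(temp.times) < 2:
        return []
    dT = np.gradient(temp.temps, temp.times)
    falling = dT < -1e-9
    clusters = []
    t = 0.0
    duration = temp.duration
    while True:
        t += rng.exponential(1.0 / spec.ramp_burst_rate)
        if t > duration:
            break
        if not bool(np.interp(t, temp.times, falling.astype(float)) > 0.5):
            continue
        n = int(rng.integers(spec.burst_size_range[0], spec.burst_size_range[1] + 1))
        isis = rng.uniform(*spec.intra_burst_isi_range, size=n - 1)
        tt = t + np.concatenate([[0.0], np.cumsum(isis)])
        clusters.append(tt[tt <= duration])
    return clusters


def generate_spike_recording(
    spec: SpikeGenSpec, temp: TemperatureTrace
) -> tuple[np.ndarray, SpikeGroundTruth]:
    """Synthesize a voltage trace from a temperature program.

    Returns ``(voltage, truth)``; voltage is sampled at ``spec.sampling_rate``
    over the temperature trace's duration, each ground-truth spike leaving a
    template extremum at its time.  A 2.5-ms refractory floor is enforced on
    the merged train (later spike dropped).
    """
    rng = np.random.default_rng(spec.seed)
    tonic = _tonic_times(spec, temp, rng)
    clusters = _burst_times(spec, temp, rng)
    burst = np.concatenate(clusters) if clusters else np.empty(0)
    times = np.concatenate([tonic, burst])
    member = np.concatenate([np.zeros(len(tonic), bool), np.ones(len(burst), bool)])
    order = np.argsort(times, kind="stable")
    times, member = times[order], member[order]
    keep = np.ones(len(times), dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if t - last < REFRACTORY_FLOOR_S:
            keep[i] = False
        else:
            last = t
    times, member = times[keep], member[keep]

    n = int(round(temp.duration * spec.sampling_rate)) + 1
    v = np.zeros(n)
    tpl = spike_template(spec)
    half = len(tpl) // 2
    for t in times:
        idx = int(round(t * spec.sampling_rate))
        lo, hi = idx - half, idx + half + 1
        tlo, thi = max(lo, 0), min(hi, n)
        v[tlo:thi] += tpl[tlo - lo : len(tpl) - (hi - thi)]
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, size=n)
    return v, SpikeGroundTruth(spike_times=times, burst_member=member)


# ---------------------------------------------------------------------------
# neuron trees


@dataclass(frozen=True)
class NeuronTreeSpec:
    """Parameters for a rasterized binary neuron arbor.

    Trees are strictly bifurcating: after the root segment, children are
    added in sibling pairs at an existing open tip, so every junction has
    degree 3 and the skeleton branch count equals ``n_segments`` by
    construction.  ``n_segments`` must therefore be odd.
    """

    n_segments: int = 7
    segment_length_range: tuple[float, float] = (25.0, 55.0)
    branch_angle_range: tuple[float, float] = (25.0, 65.0)  # degrees off parent
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValidationError("n_segments must be >= 1")
        if self.n_segments % 2 == 0:
            raise ValidationError(
                "n_segments must be odd: children are attached in bifurcating pairs"
            )
        if self.segment_length_range[0] < 4:
            raise ValidationError("segments must be at least 4 px long")


@dataclass(frozen=True)
class TreeGroundTruth:
    n_segments: int
    total_length: float                     # summed Euclidean segment length
    segments: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_segments": self.n_segments,
                "total_length": self.total_length,
                "segments": [[list(a), list(b)] for a, b in self.segments],
            }
        )


def _seg_pixels(p0, p1):
    rr, cc = _line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
    return set(zip(rr.tolist(), cc.tolist()))


def generate_neuron_image(spec: NeuronTreeSpec) -> tuple[np.ndarray, TreeGroundTruth]:
    """Rasterize a random bifurcating tree of straight 1-px branches.

    Placement is reject-and-resample: a candidate branch that would leave
    the image margin or pass within 3 px of a non-adjacent existing branch
    is redrawn; persistent failure raises a validation error suggesting a
    larger image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    margin = 6

    for attempt in range(40):
        root_len = rng.uniform(*spec.segment_length_range)
        ang = rng.uniform(0, 2 * np.pi)
        p0 = np.array([h / 2.0, w / 2.0]) - (root_len / 2) * np.array([np.sin(ang), np.cos(ang)])
        p1 = p0 + root_len * np.array([np.sin(ang), np.cos(ang)])
        segs = [(tuple(np.round(p0).astype(int)), tuple(np.round(p1).astype(int)), ang)]
        pixels = _seg_pixels(segs[0][0], segs[0][1])
        open_tips = [(segs[0][1], ang)]
        ok = True
        while len(segs) < spec.n_segments:
            if not open_tips:
                ok = False
                break
            ti = int(rng.integers(len(open_tips)))
            tip, tip_ang = open_tips.pop(ti)
            pair = []
            placed = True
            for sign in (+1, -1):
                success = False
                for _ in range(30):
                    dev = np.deg2rad(rng.uniform(*spec.branch_angle_range))
                    a = tip_ang + sign * dev
                    ln = rng.uniform(*spec.segment_length_range)
                    q = np.array(tip) + ln * np.array([np.sin(a), np.cos(a)])
                    if not (margin <= q[0] < h - margin and margin <= q[1] < w - margin):
                        continue
                    qi = tuple(np.round(q).astype(int))
                    newpix = _seg_pixels(tip, qi)
                    # ignore pixels near the attachment point when testing overlap
                    near_tip = {
                        (r, c)
                        for (r, c) in newpix
                        if (r - tip[0]) ** 2 + (c - tip[1]) ** 2 <= 9
                    }
                    body = newpix - near_tip
                    clash = any(
                        (r + dr, c + dc) in pixels
                        for (r, c) in body
                        for dr in (-1, 0, 1)
                        for dc in (-1, 0, 1)
                    )
                    if clash:
                        continue
                    pair.append((tip, qi, a, newpix))
                    pixels |= newpix
                    success = True
                    break
                if not success:
                    placed = False
                    break
            if not placed:
                ok = False
                break
            for tip0, qi, a, _np_ in pair:
                segs.append((tip0, qi, a))
                open_tips.append((qi, a))
        if ok and len(segs) == spec.n_segments:
            img = np.zeros((h, w), dtype=bool)
            for (a, b, _) in segs:
                rr, cc = _line(a[0], a[1], b[0], b[1])
                img[rr, cc] = True
            total = float(
                sum(np.hypot(b[0] - a[0], b[1] - a[1]) for (a, b, _) in segs)
            )
            truth = TreeGroundTruth(
                n_segments=len(segs),
                total_length=total,
                segments=tuple((a, b) for (a, b, _) in segs),
            )
            return img, truth
    raise ValidationError("could not place all segments; increase image_size")


# ---------------------------------------------------------------------------
# touch tables


def generate_touch_table(
    n_subjects: int,
    behavior_probabilities: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5),
    seed: int = 0,
    n_trials: int = 3,
):
    """Bernoulli gentle-touch behavior table.

    Returns ``(table, truth)`` where ``table`` is a DataFrame with columns
    ``subject, trial, pause, head_withdrawal, head_cast, reverse`` and
    ``truth`` maps each subject to its summed score.
    """
    import pandas as pd

    probs = np.asarray(behavior_probabilities, dtype=float)
    if probs.shape != (4,) or np.any((probs < 0) | (probs > 1)):
        raise ValidationError("behavior_probabilities must be 4 values in [0, 1]")
    rng = np.random.default_rng(seed)
    flags = rng.uniform(size=(n_subjects, n_trials, 4)) < probs
    rows = []
    cols = ["pause", "head_withdrawal", "head_cast", "reverse"]
    for s in range(n_subjects):
        for t in range(n_trials):
            rows.append([s, t, *flags[s, t].astype(int)])
    table = pd.DataFrame(rows, columns=["subject", "trial", *cols])
    truth = {"subject_sums": flags.sum(axis=(1, 2)).astype(int).tolist()}
    return table, truth
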