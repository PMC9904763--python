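"""Cold-evoked spike-train analysis.

Covers extracellular spike detection (robust MAD threshold with a
refractory merge), the inter-spike-interval burst rule — a spike is
"bursting" when either flanking ISI is shorter than 0.2 s, tonic otherwise —
10-s binned firing statistics, temperature-epoch assignment (room, 20, 15,
10 degC holds), per-epoch firing rates, latency to peak activity, and
population heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .synthetic import TemperatureTrace

DEFAULT_MAX_ISI_S = 0.2  # burst criterion: ISI < 0.2 s


@dataclass(frozen=True)
class VoltageTrace:
    samples: np.ndarray
    sampling_rate: float = 10_000.0
    start_time: float = 0.0

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1:
            raise ValidationError("samples must be 1-D")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass(frozen=True)
class SpikeTrain:
    spike_times: np.ndarray
    recording_duration: float

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValidationError("spike_times must be 1-D")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("spike_times must be strictly increasing")
        if len(t) and (t[0] < 0 or t[-1] > self.recording_duration + 1e-9):
            raise ValidationError("spike times must lie within [0, recording_duration]")
        object.__setattr__(self, "spike_times", t)

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class BurstLabeling:
    """Per-spike bursting/tonic labels plus maximal burst intervals."""

    bursting: np.ndarray                       # bool per spike
    burst_intervals: tuple[tuple[int, int], ...]  # (start idx, end idx) inclusive

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.bursting, "bursting", "tonic")


def detect_spikes(
    trace: VoltageTrace,
    k_mad: float = 5.0,
    refractory_ms: float = 2.0,
    polarity: str = "auto",
) -> SpikeTrain:
    """Threshold-based spike extraction.

    The threshold sits ``k_mad`` robust standard deviations
    (1.4826 x MAD) from the median, on the positive or negative side
    (``polarity`` in {"pos", "neg", "auto"}; auto picks the side with the
    larger extreme deviation).  Each supra-threshold excursion yields one
    spike at its extremum; extrema closer than the refractory period are
    merged, keeping the larger deflection.
    """
    v = trace.samples
    if trace.duration < 1.0:
        raise ValidationError("need >= 1 s of data for spike detection")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    sigma = 1.4826 * mad
    if sigma == 0:
        # noise-free traces: sparse spikes leave the MAD at zero; fall back to
        # the ordinary SD so clean recordings are still thresholdable
        sigma = float(v.std())
    if sigma == 0:
        warnings.warn("zero-variance trace: no spikes detected", stacklevel=2)
        return SpikeTrain(np.empty(0), trace.duration)
    if polarity == "auto":
        polarity = "pos" if (v.max() - med) >= (med - v.min()) else "neg"
    x = v - med if polarity == "pos" else med - v
    thr = k_mad * sigma
    above = x > thr
    if not above.any():
        return SpikeTrain(np.empty(0), trace.duration)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(x)]])
    peaks = []
    amps = []
    for s, e in zip(starts, ends):
        i = s + int(np.argmax(x[s:e]))
        peaks.append(i)
        amps.append(x[i])
    # refractory merge: keep the larger extremum of any pair too close
    ref = int(round(refractory_ms * 1e-3 * trace.sampling_rate))
    kept: list[int] = []
    for i, a in sorted(zip(peaks, amps)):
        if kept and i - kept[-1] < ref:
            if a > x[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    times = np.asarray(kept, dtype=float) / trace.sampling_rate + trace.start_time
    return SpikeTrain(times, trace.duration)


def label_bursts(train: SpikeTrain, max_isi: float = DEFAULT_MAX_ISI_S) -> BurstLabeling:
    """ISI burst rule: a spike is bursting iff either flanking ISI < ``max_isi``.

    Maximal runs of consecutive bursting spikes form the burst intervals;
    every burst interval contains at least two spikes by construction.
    Empty and singleton trains are entirely tonic.
    """
    t = train.spike_times
    n = len(t)
    if n < 2:
        return BurstLabeling(np.zeros(n, dtype=bool), ())
    isi = np.diff(t)
    short = isi < max_isi  # strict
    bursting = np.zeros(n, dtype=bool)
    bursting[:-1] |= short
    bursting[1:] |= short
    intervals = []
    i = 0
    while i < n:
        if bursting[i]:
            j = i
            while j + 1 < n and bursting[j + 1]:
                j += 1
            intervals.append((i, j))
            i = j + 1
        else:
            i += 1
    return BurstLabeling(bursting, tuple(intervals))


@dataclass(frozen=True)
class BinnedActivity:
    """Firing rate and bursting-spike fraction in fixed-width time bins."""

    bin_edges: np.ndarray          # len nbins + 1
    rate: np.ndarray               # Hz, count / actual bin duration
    bursting_fraction: np.ndarray  # NaN where a bin holds no spikes
    counts: np.ndarray
    partial_final_bin: bool

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_durations(self) -> np.ndarray:
        return np.diff(self.bin_edges)


def binned_activity(
    train: SpikeTrain, labeling: BurstLabeling | None = None, bin_s: float = 10.0
) -> BinnedActivity:
    """Bin a train into ``bin_s``-second bins (final partial bin kept, flagged).

    Rates divide by each bin's actual duration, so
    sum(rate x duration) == total spike count always holds.
    """
    if train.recording_duration <= 0:
        raise ValidationError("recording_duration must be > 0")
    dur = train.recording_duration
    nfull = int(np.floor(dur / bin_s + 1e-12))
    edges = np.arange(nfull + 1) * bin_s
    partial = dur - edges[-1] > 1e-9
    if partial or nfull == 0:
        edges = np.append(edges, dur)
    t = train.spike_times
    idx = np.minimum(np.searchsorted(edges, t, side="right") - 1, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float) if len(t) else np.zeros(
        len(edges) - 1
    )
    widths = np.diff(edges)
    rate = counts / widths
    frac = np.full(len(counts), np.nan)
    if labeling is not None and len(t):
        bcounts = np.bincount(idx, weights=labeling.bursting.astype(float), minlength=len(counts))
        nz = counts > 0
        frac[nz] = bcounts[nz] / counts[nz]
    return BinnedActivity(
        bin_edges=edges,
        rate=rate,
        bursting_fraction=frac,
        counts=counts,
        partial_final_bin=bool(partial),
    )


@dataclass(frozen=True)
class EpochWindow:
    label: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def assign_epochs(
    temp: TemperatureTrace,
    setpoints: tuple[float, ...] = (20.0, 15.0, 10.0),
    tol: float = 0.5,
    min_hold: float = 10.0,
    cooling_rate: float = -0.05,
    sustain_s: float = 1.0,
) -> list[EpochWindow]:
    """Locate the room baseline and each setpoint's hold window.

    A setpoint epoch is the maximal contiguous window with
    ``|T - setpoint| <= tol`` lasting at least ``min_hold`` seconds (the
    longest such run if several).  "room" is the window before the first
    sustained cooling onset (dT/dt below ``cooling_rate`` for at least
    ``sustain_s``).  Setpoints never reached are absent, with a warning.
    """
    t, T = temp.times, temp.temps
    epochs: list[EpochWindow] = []
    dT = np.gradient(T, t)
    cooling = dT < cooling_rate
    onset = None
    run_start = None
    for i, c in enumerate(cooling):
        if c:
            if run_start is None:
                run_start = i
            if t[i] - t[run_start] >= sustain_s:
                onset = run_start
                break
        else:
            run_start = None
    if onset is not None and t[onset] > 0:
        epochs.append(EpochWindow("room", float(t[0]), float(t[onset])))
    elif onset is None:
        epochs.append(EpochWindow("room", float(t[0]), float(t[-1])))

    for sp in setpoints:
        near = np.abs(T - sp) <= tol
        best = None
        i = 0
        n = len(t)
        while i < n:
            if near[i]:
                j = i
                while j + 1 < n and near[j + 1]:
                    j += 1
                span = t[j] - t[i]
                if span >= min_hold and (best is None or span > best[1] - best[0]):
                    best = (t[i], t[j])
                i = j + 1
            else:
                i += 1
        if best is None:
            warnings.warn(f"setpoint {sp} degC never held >= {min_hold} s", stacklevel=2)
        else:
            epochs.append(EpochWindow(f"{sp:g}C", float(best[0]), float(best[1])))
    return epochs


@dataclass(frozen=True)
class EpochStats:
    label: str
    window: tuple[float, float]
    spike_count: int
    mean_rate: float
    bursting_fraction: float  # NaN if no spikes


def epoch_stats(
    train: SpikeTrain, labeling: BurstLabeling, epochs: list[EpochWindow]
) -> list[EpochStats]:
    """Per-epoch spike count, mean firing rate, and bursting-spike fraction."""
    spans = sorted((e.start, e.end) for e in epochs)
    for (s1, e1), (s2, _) in zip(spans[:-1], spans[1:]):
        if s2 < e1 - 1e-9:
            raise ValidationError("epochs must be non-overlapping")
    out = []
    t = train.spike_times
    for ep in epochs:
        if ep.duration <= 0:
            raise ValidationError(f"zero-length epoch {ep.label!r}")
        sel = (t >= ep.start) & (t < ep.end)
        k = int(sel.sum())
        frac = float(labeling.bursting[sel].mean()) if k else float("nan")
        out.append(
            EpochStats(
                label=ep.label,
                window=(ep.start, ep.end),
                spike_count=k,
                mean_rate=k / ep.duration,
                bursting_fraction=frac,
            )
        )
    return out


def latency_to_peak(binned: BinnedActivity, onset_s: float = 0.0) -> float:
    """Time from onset to the center of the maximum-rate bin (earliest on ties).

    NaN when no bin holds any spikes.
    """
    if binned.bin_edges[0] - 1e-9 > onset_s or onset_s > binned.bin_edges[-1] + 1e-9:
        raise ValidationError("onset must lie within the binned recording")
    if not np.any(binned.rate > 0):
        return float("nan")
    i = int(np.argmax(binned.rate))  # argmax takes the earliest maximal bin
    return float(binned.bin_centers[i] - onset_s)


def population_heatmap(binned_list: list[BinnedActivity]) -> np.ndarray:
    """Stack per-sample binned rates into a samples x bins matrix."""
    if not binned_list:
        raise ValidationError("need >= 1 sample")
    ref = binned_list[0].bin_edges
    for b in binned_list[1:]:
        if len(b.bin_edges) != len(ref) or not np.allclose(b.bin_edges, ref):
            raise ValidationError("all samples must share the same bin structure")
    return np.vstack([b.rate for b in binned_list])
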