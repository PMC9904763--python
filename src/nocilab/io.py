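"""File formats, run configuration, and the pipeline driver.

All traces travel as headered CSV in SI-ish units (seconds, degC, px);
image stacks as multi-page TIFF or lexically ordered PNG directories;
ground truth and summaries as JSON.  Every pipeline run logs its fully
resolved configuration, seed, and a config hash so results can be
reproduced from the log alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .ephys import BinnedActivity, SpikeTrain, VoltageTrace
from .errors import PipelineError, ValidationError
from .imaging import ImageStack, LengthTrace
from .synthetic import TemperatureTrace


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run; JSON round-trip stable."""

    seed: int = 0
    fps: float = 30.0
    window_s: float = 5.0
    ct_threshold_source: str = "fixed_default"   # or "control_cohort"
    ct_decrease_threshold: float = 0.30
    burst_max_isi: float = 0.2
    bin_s: float = 10.0
    epoch_setpoints: tuple[float, ...] = (20.0, 15.0, 10.0)
    epoch_tol: float = 0.5
    stats_family_size: int | None = None
    stats_tails: str = "two"
    out_dir: str = "."

    def __post_init__(self):
        for name in ("fps", "window_s", "burst_max_isi", "bin_s", "epoch_tol"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.stats_tails not in ("one", "two"):
            raise ValidationError("stats_tails must be 'one' or 'two'")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["epoch_setpoints"] = list(self.epoch_setpoints)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "epoch_setpoints" in d:
            d["epoch_setpoints"] = tuple(d["epoch_setpoints"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# image stacks


def read_image_stack(path, fps: float = 30.0, pixel_size: float | None = None) -> ImageStack:
    """Read a multi-page TIFF, or a directory of lexically ordered PNGs."""
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"no such input: {p}")
    if p.is_dir():
        files = sorted(p.glob("*.png"))
        if not files:
            raise ValidationError(f"directory {p} holds no PNG frames")
        frames = []
        shape = None
        for f in files:
            try:
                img = np.asarray(iio.imread(f))
            except Exception as e:  # noqa: BLE001
                raise ValidationError(f"unreadable frame {f}: {e}") from e
            if img.ndim == 3:
                img = img.mean(axis=-1)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValidationError(f"mixed frame shapes: {f} is {img.shape}, expected {shape}")
            frames.append(img.astype(np.float32))
        arr = np.stack(frames)
    else:
        try:
            arr = np.asarray(tifffile.imread(p))
        except Exception as e:  # noqa: BLE001
            raise ValidationError(f"unreadable TIFF {p}: {e}") from e
        if arr.ndim == 2:
            arr = arr[None]
        arr = arr.astype(np.float32)
    return ImageStack(frames=arr, frame_interval=1.0 / fps, pixel_size=pixel_size)


def write_image_stack(stack: ImageStack, path, png_dir: bool = False) -> None:
    """Write frames as multi-page TIFF (default) or a numbered PNG sequence."""
    p = Path(path)
    frames = np.clip(stack.frames, 0, 255).astype(np.uint8)
    if png_dir:
        p.mkdir(parents=True, exist_ok=True)
        for i, fr in enumerate(frames):
            iio.imwrite(p / f"{i:05d}.png", fr)
    else:
        p.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(p, frames)


# ---------------------------------------------------------------------------
# trace CSV

_EXPECTED = {
    "voltage": ["time_s", "value"],
    "temperature": ["time_s", "celsius"],
    "spikes": ["time_s"],
    "lengths": ["frame", "time_s", "length_px", "normalized", "valid"],
}


def read_trace_csv(path, kind: str):
    """Read a typed trace CSV: voltage, temperature, spikes, or lengths."""
    if kind not in _EXPECTED:
        raise ValidationError(f"unknown trace kind {kind!r}")
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"no such input: {p}")
    df = pd.read_csv(p)
    missing = [c for c in _EXPECTED[kind] if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{p}: missing columns {missing}; expected header {_EXPECTED[kind]}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError(f"{p}: time column must be strictly increasing")
    if kind == "voltage":
        dt = np.diff(t)
        fs = 1.0 / float(np.median(dt)) if len(dt) else 10_000.0
        return VoltageTrace(df["value"].to_numpy(dtype=float), sampling_rate=fs, start_time=float(t[0]) if len(t) else 0.0)
    if kind == "temperature":
        return TemperatureTrace(times=t, temps=df["celsius"].to_numpy(dtype=float))
    if kind == "spikes":
        dur = float(df.attrs.get("duration", t[-1] if len(t) else 0.0))
        return SpikeTrain(t, recording_duration=dur)
    return LengthTrace(
        times=t,
        length_px=df["length_px"].to_numpy(dtype=float),
        normalized=df["normalized"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
    )


def write_length_trace(trace: LengthTrace, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(trace.times)),
            "time_s": trace.times,
            "length_px": trace.length_px,
            "normalized": trace.normalized,
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(path, index=False)


def write_binned(binned: BinnedActivity, path) -> None:
    pd.DataFrame(
        {
            "bin_start_s": binned.bin_edges[:-1],
            "bin_end_s": binned.bin_edges[1:],
            "rate_hz": binned.rate,
            "bursting_fraction": binned.bursting_fraction,
            "count": binned.counts,
        }
    ).to_csv(path, index=False)


def read_binned(path) -> BinnedActivity:
    df = pd.read_csv(path)
    edges = np.append(df["bin_start_s"].to_numpy(float), df["bin_end_s"].to_numpy(float)[-1])
    widths = np.diff(edges)
    return BinnedActivity(
        bin_edges=edges,
        rate=df["rate_hz"].to_numpy(float),
        bursting_fraction=df["bursting_fraction"].to_numpy(float),
        counts=df["count"].to_numpy(float),
        partial_final_bin=bool(len(widths) and not np.isclose(widths[-1], widths[0])),
    )


def write_matrix(mat: np.ndarray, path, prefix: str = "bin") -> None:
    pd.DataFrame(mat, columns=[f"{prefix}{i}" for i in range(mat.shape[1])]).to_csv(
        path, index_label="row"
    )


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run a seeded simulate -> analyze demonstration pipeline.

    Generates a small CT cohort and a cold-ramp recording from
    ``config.seed``, analyzes both, and writes CSV/JSON artifacts plus a
    log carrying the resolved config and its hash under
    ``config.out_dir``.  Identical config implies identical outputs.
    """
    from . import ephys, imaging, synthetic

    stages = stages or ["simulate", "ct", "ephys"]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash}
    threshold = imaging.CTThreshold(
        config.ct_decrease_threshold, source=config.ct_threshold_source
    )
    try:
        if "ct" in stages:
            results, traces = [], []
            for i in range(8):
                spec = synthetic.LarvaSceneSpec(
                    n_frames=40,
                    frame_rate=8.0,
                    contraction_magnitude=0.4 if i % 2 else 0.1,
                    seed=config.seed * 1000 + i,
                )
                frames, _ = synthetic.generate_larva_stack(spec)
                stack = imaging.ImageStack(frames=frames, frame_interval=1.0 / spec.frame_rate)
                trace = imaging.length_trace(stack, window_s=config.window_s)
                if trace.discarded:
                    continue
                traces.append(trace)
                results.append(imaging.classify_ct(trace, threshold))
                write_length_trace(trace, out / f"larva_{i:02d}.csv")
            cohort = imaging.summarize_cohort(results, traces)
            write_matrix(cohort.heatmap, out / "ct_heatmap.csv")
            summary["ct"] = {
                "n": cohort.n,
                "pct_strong": cohort.pct_strong,
                "pct_strong_se": cohort.pct_strong_se,
                "mean_peak": cohort.mean_peak,
                "sem_peak": cohort.sem_peak,
                "length_cutoff": threshold.length_cutoff,
            }
        if "ephys" in stages:
            protocol = synthetic.TemperatureProtocol.ramp_and_hold(
                setpoints=config.epoch_setpoints, room_s=20.0, hold_s=30.0, ramp_rate=1.0
            )
            temp = synthetic.generate_temperature_trace(protocol, dt=0.1)
            spec = synthetic.SpikeGenSpec(seed=config.seed, noise_sd=0.05)
            v, truth = synthetic.generate_spike_recording(spec, temp)
            trace = VoltageTrace(v, sampling_rate=spec.sampling_rate)
            train = ephys.detect_spikes(trace)
            labeling = ephys.label_bursts(train, max_isi=config.burst_max_isi)
            binned = ephys.binned_activity(train, labeling, bin_s=config.bin_s)
            write_binned(binned, out / "binned.csv")
            epochs = ephys.assign_epochs(
                temp, setpoints=config.epoch_setpoints, tol=config.epoch_tol
            )
            estats = ephys.epoch_stats(train, labeling, epochs)
            summary["ephys"] = {
                "n_spikes": len(train),
                "n_bursting": int(labeling.bursting.sum()),
                "epochs": {
                    e.label: {"rate_hz": e.mean_rate, "spike_count": e.spike_count}
                    for e in estats
                },
            }
    except (ValidationError, OSError) as e:
        raise PipelineError("/".join(stages), str(e)) from e
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run_log.json").write_text(
        json.dumps({"config": json.loads(config.to_json()), "hash": config.config_hash}, indent=2)
    )
    return summary
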