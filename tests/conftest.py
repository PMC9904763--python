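import numpy as np
import pytest

from nocilab import synthetic as syn


@pytest.fixture(scope="session")
def ramp_protocol() -> syn.TemperatureProtocol:
    """Room hold, then ramp-and-hold steps to 20, 15, 10 degC."""
    return syn.TemperatureProtocol.ramp_and_hold(room_s=20.0, hold_s=30.0, ramp_rate=1.0)


@pytest.fixture(scope="session")
def ramp_temperature(ramp_protocol) -> syn.TemperatureTrace:
    return syn.generate_temperature_trace(ramp_protocol, dt=0.1)


def small_scene(m: float, seed: int, **kw) -> syn.LarvaSceneSpec:
    """A compact scene (8 fps, 5 s) that keeps image analysis fast in tests."""
    kw.setdefault("n_frames", 40)
    kw.setdefault("frame_rate", 8.0)
    return syn.LarvaSceneSpec(contraction_magnitude=m, seed=seed, **kw)


def match_trains(true_times: np.ndarray, det_times: np.ndarray, tol: float = 1e-3):
    """Greedy one-to-one matching; returns (precision, recall, f1)."""
    used: set[int] = set()
    tp = 0
    for t in true_times:
        if len(det_times) == 0:
            break
        j = int(np.argmin(np.abs(det_times - t)))
        if abs(det_times[j] - t) <= tol and j not in used:
            used.add(j)
            tp += 1
    prec = tp / max(len(det_times), 1)
    rec = tp / max(len(true_times), 1)
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1
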