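import numpy as np
import pandas as pd
import pytest

from tovaosc import preprocess as pre
from tovaosc import simulate as sim

FS = 512.0


def make_epochs(data, fs=FS, labels=None, rt=0.4, condition="correct_response",
                half="H1", time0=-1.0):
    """EpochSet from a raw trials x channels x samples array."""
    data = np.asarray(data, dtype=float)
    n, n_ch, n_s = data.shape
    labels = tuple(labels) if labels is not None else tuple(f"ch{i}" for i in range(n_ch))
    rt = np.broadcast_to(np.asarray(rt, dtype=float), n)
    meta = pd.DataFrame(
        {
            "condition": condition,
            "half": half,
            "rt_s": rt,
            "onset_s": 2.0 + np.arange(n) * 2.0,
        }
    )
    return pre.EpochSet(
        data=data,
        time_s=time0 + np.arange(n_s) / fs,
        fs_hz=fs,
        channel_labels=labels,
        meta=meta,
    )


def oscillation_epochs(freq_hz, phases, n_samples=1024, fs=FS, amp=1.0,
                       n_channels=1, labels=None):
    """One sinusoidal trial per phase, identical across channels."""
    t = np.arange(n_samples) / fs - 1.0
    x = amp * np.sin(2 * np.pi * freq_hz * t[None, :] + np.asarray(phases)[:, None])
    data = np.repeat(x[:, None, :], n_channels, axis=1)
    return make_epochs(data, fs=fs, labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_recording():
    """Small artifact-free synthetic session used by several modules."""
    sched = sim.make_schedule("H1", 8, 24, seed=42)
    record = sim.simulate_behavior(sched, seed=43)
    params = sim.GenParams(seed=44, blink_rate_per_min=0.0)
    return sim.synthesize_eeg(sched, record, params)


@pytest.fixture(scope="session")
def clean_epochs(clean_recording):
    ep = pre.epoch(clean_recording)
    ep, _ = pre.reject_invalid_trials(ep)
    return pre.baseline_correct(ep)
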