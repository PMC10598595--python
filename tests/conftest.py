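import numpy as np
import pytest

from rrbscope.epochs import EpochSet
from rrbscope.montage import standard_1020
from rrbscope.spectral import ConnectivityMatrix


@pytest.fixture(scope="session")
def montage20():
    return standard_1020()


def make_epochs(data, sample_rate=250.0, tmin_ms=-1000.0, conditions=None,
                channels=None, subject_id="S01", **kw):
    """EpochSet from a raw (trials, channels, samples) array."""
    data = np.asarray(data, float)
    n_trials, n_ch = data.shape[:2]
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(n_ch))
    if conditions is None:
        conditions = np.array(["HRIS"] * n_trials, dtype=object)
    return EpochSet(subject_id=subject_id, data=data, sample_rate=sample_rate,
                    tmin_ms=tmin_ms, channels=channels, conditions=conditions, **kw)


def sine_epochs(freq=10.0, amp=1.0, n_trials=2, n_ch=2, sample_rate=250.0,
                tmin_ms=-1000.0, n_samples=750, phase=0.0):
    t = (tmin_ms / 1000.0) + np.arange(n_samples) / sample_rate
    sig = amp * np.sin(2 * np.pi * freq * t + phase)
    data = np.tile(sig, (n_trials, n_ch, 1))
    return make_epochs(data, sample_rate=sample_rate, tmin_ms=tmin_ms)


def make_matrix(values, subject_id="S01", condition="HRIS", channels=None):
    values = np.asarray(values, float)
    n = values.shape[0]
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(n))
    return ConnectivityMatrix(subject_id=subject_id, condition=condition,
                              values=values, channels=channels)


def random_connectivity(rng, channels, subject_id="S", condition="HRIS",
                        bump_edges=(), bump=0.0):
    """Beta-noise symmetric matrix with an optional planted additive bump."""
    n = len(channels)
    v = rng.beta(2.0, 8.0, size=(n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    for i, j in bump_edges:
        v[i, j] += bump
        v[j, i] += bump
    v = np.clip(v, 0.0, 1.0)
    return ConnectivityMatrix(subject_id=subject_id, condition=condition,
                              values=v, channels=channels)
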