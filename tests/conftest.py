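import numpy as np
import pytest

from pgeskit import CANONICAL_CHANNELS, Snippet, SynthConfig, generate_dataset

FS = 200.0
N = 2000  # 10 s at 200 Hz


def make_snippet(samples, fs=FS, **kwargs):
    samples = np.asarray(samples, dtype=float)
    names = kwargs.pop("channel_names", CANONICAL_CHANNELS[: samples.shape[0]])
    return Snippet(samples=samples, fs=fs, channel_names=names, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_snippet(rng):
    """A 10-channel, 10-s snippet of broadband random activity."""
    return make_snippet(rng.normal(0.0, 20.0, (10, N)))


def sinusoid(freq, amp=1.0, n=N, fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture(scope="session")
def easy_dataset():
    """Small patient-disjoint dataset on the easy generator configuration.

    Shared across evaluation tests; acceptance tests build their own
    larger dataset.
    """
    cfg = SynthConfig(n_patients=10, suppression_amp_uv=5.0,
                      activity_amp_uv=40.0, noise_sd_uv=2.0, seed=0)
    return generate_dataset(cfg, snippets_per_patient=6, split=(0.6, 0.4), seed=77)
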