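import numpy as np
import pytest

from dhmea.io import ArrayGeometry, SpikeTable, StimulusEvent
from dhmea.preprocess import EpochSpec, EpochTensor


@pytest.fixture
def geometry():
    return ArrayGeometry()


def dummy_events(n, gap_s=10.0, start_s=50.0, freq=0.1, train_id="t", label="x", amplitude=5.0):
    return [
        StimulusEvent(start_s + i * gap_s, "electrical", amplitude, 2.0, train_id, i, freq, label)
        for i in range(n)
    ]


@pytest.fixture
def make_events():
    return dummy_events


@pytest.fixture
def make_tensor():
    """Factory for small random raw tensors with consistent events."""

    def _make(rng, n_stim=5, n_chan=16, pre_ms=10.0, post_ms=40.0, lam=2.0):
        spec = EpochSpec(pre_ms=pre_ms, post_ms=post_ms, bin_ms=1.0)
        values = rng.poisson(lam, (n_stim, n_chan, spec.n_bins))
        return EpochTensor(values, spec, dummy_events(n_stim), stage="raw")

    return _make


@pytest.fixture
def make_full_tensor():
    """Factory for default-geometry tensors spanning the standard 1.1 s epoch."""

    def _make(rng, n_stim=6, n_chan=16, lam=0.5):
        spec = EpochSpec()
        values = rng.poisson(lam, (n_stim, n_chan, spec.n_bins))
        return EpochTensor(values, spec, dummy_events(n_stim), stage="raw")

    return _make


@pytest.fixture
def random_spikes():
    def _make(rng, n=1000, t_max=100.0, n_channels=16):
        return SpikeTable(
            rng.uniform(0, t_max, n), rng.integers(1, n_channels + 1, n), n_channels
        )

    return _make
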