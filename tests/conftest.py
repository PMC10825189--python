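import numpy as np
import pytest

from dnadevice.simkit import IntensityTrace, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def no_bleach_config():
    """Random-birth study conditions with bleaching disabled."""
    return SimConfig(
        gene_extension_length=1980.0,
        initiation_rate=0.01,
        bleach_time=float("inf"),
        duration=7200.0,
        seed=11,
    )


@pytest.fixture
def bleach_config():
    """Random-birth study conditions with the 1.5 min bleaching time."""
    return SimConfig(
        gene_extension_length=1980.0,
        initiation_rate=0.01,
        bleach_time=90.0,
        duration=3600.0,
        seed=7,
    )


def make_trace(values, dt=4.0, trace_id="t"):
    values = np.asarray(values, dtype=float)
    return IntensityTrace(t=np.arange(len(values)) * dt, intensity=values, trace_id=trace_id)
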