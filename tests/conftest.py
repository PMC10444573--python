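import numpy as np
import pytest

from hnburst.reduced_model import ReducedModelParams
from hnburst.trace import Trace


@pytest.fixture(scope="session")
def reduced_params():
    return ReducedModelParams()


@pytest.fixture(scope="session")
def reduced_trace_03():
    """Steady bursting of the reduced model at the standard 0.3-nA condition."""
    from hnburst.reduced_model import simulate_2d

    return simulate_2d(ReducedModelParams(ipump_max=0.3), 60.0)


def make_spike_trace(spike_times, fs=5000.0, duration=None, baseline=-0.05,
                     spike_height=0.04, spike_half_width=0.004):
    """Synthetic voltage trace: triangular spikes on a flat baseline."""
    spike_times = np.asarray(spike_times, dtype=float)
    if duration is None:
        duration = (spike_times.max() if spike_times.size else 1.0) + 0.5
    t = np.arange(0.0, duration, 1.0 / fs)
    v = np.full_like(t, baseline)
    for ts in spike_times:
        m = np.abs(t - ts) < spike_half_width
        v[m] = baseline + spike_height * (
            1.0 - np.abs(t[m] - ts) / spike_half_width)
    z = np.zeros_like(t)
    return Trace(t, v, z, z, np.full_like(t, 0.012))


@pytest.fixture
def spike_trace_factory():
    return make_spike_trace
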