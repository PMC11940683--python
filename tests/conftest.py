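import numpy as np
import pytest

from hrvbalance import simulate as sim
from hrvbalance.series import RRSeries


@pytest.fixture(scope="session")
def default_recording():
    """One deterministic three-phase recording with study-default calibration."""
    return sim.simulate_recording(seed=1)


@pytest.fixture(scope="session")
def ipfm_series():
    """A single-phase IPFM series at baseline calibration (~800 s)."""
    spec = sim.ModulatorSpec(mean_rr=680.0, lf_amp=35.9, hf_amp=24.3, noise_sd=5.0)
    beats = sim.ipfm_beat_times(spec, 800.0, seed=11)
    return RRSeries(intervals=np.diff(np.concatenate([[0.0], beats])) * 1000.0)


@pytest.fixture(scope="session")
def jury_default():
    return sim.simulate_jury(seed=21)


def constant_series(rr_ms: float = 800.0, n: int = 300) -> RRSeries:
    return RRSeries(intervals=np.full(n, rr_ms))
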