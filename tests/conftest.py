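import numpy as np
import pytest

from ivsi import CycleParams, StrainTrace, ValveEvents, simulate_cycle


@pytest.fixture(scope="session")
def noiseless_cycle():
    """One noiseless simulated beat (radial + longitudinal, endo + epi)."""
    return simulate_cycle(CycleParams(noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_radial_cycle():
    """Noiseless beat restricted to radial endocardial strain."""
    return simulate_cycle(CycleParams(noise_sd=0.0), directions=("radial",),
                          layers=("endocardial",))


@pytest.fixture
def events_50_68():
    """Valve events of the worked windowing example (times in seconds)."""
    return ValveEvents(cycle_start=0.0, avc_time=0.050, mvo_time=0.068,
                       cycle_end=0.140)


def make_trace(values, fs=1000.0, *, kind="strain", direction="radial",
               layer="endocardial", segment_id=1, unit=None):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) / fs
    return StrainTrace(time=t, values=values, direction=direction,
                       layer=layer, segment_id=segment_id, kind=kind,
                       unit=unit)


@pytest.fixture
def trace_factory():
    return make_trace
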