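import numpy as np
import pytest

from tauhcn.traces import StepProtocol, Trace


@pytest.fixture(scope="session")
def step_protocol() -> StepProtocol:
    """The standard hyperpolarizing current step (-100 pA, 500 ms, -80 mV)."""
    return StepProtocol()


def make_voltage_trace(samples, dt=0.05, protocol=None, **kw) -> Trace:
    return Trace(dt=dt, samples=np.asarray(samples, dtype=float), unit="mV",
                 protocol=protocol or StepProtocol(), **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20259)
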