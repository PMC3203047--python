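import logging

import numpy as np
import pytest

from singlechan import (
    ASYMMETRIC_BUFFER,
    SYMMETRIC_BUFFER,
    BufferCondition,
    CurrentTrace,
    IdealizationParams,
    VoltageProtocol,
)
from singlechan.simulate import default_channel_model

# warnings from intentionally aliased fixture dwells are noise in test output
logging.getLogger("singlechan").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def symmetric_buffer() -> BufferCondition:
    return SYMMETRIC_BUFFER


@pytest.fixture(scope="session")
def asymmetric_buffer() -> BufferCondition:
    return ASYMMETRIC_BUFFER


@pytest.fixture(scope="session")
def channel_model():
    """Reference rectifying three-level model with 2 pA noise."""
    return default_channel_model(noise_sd_pA=2.0)


@pytest.fixture
def ideal_params() -> IdealizationParams:
    return IdealizationParams(threshold_k=4.0, min_dwell_s=1e-3, e_rev_assumed_mV=0.0)


def make_step_trace(
    current_pA: np.ndarray,
    voltage_mV: float = 100.0,
    sample_rate_Hz: float = 5000.0,
    buffer: BufferCondition = SYMMETRIC_BUFFER,
    trace_id: str = "test",
) -> CurrentTrace:
    """Wrap a raw current array in a constant-voltage trace."""
    n = len(current_pA)
    proto = VoltageProtocol("step", voltage_mV, voltage_mV, n / sample_rate_Hz)
    t = np.arange(n) / sample_rate_Hz
    return CurrentTrace(
        time_s=t,
        current_pA=np.asarray(current_pA, dtype=float),
        voltage_mV=np.full(n, voltage_mV),
        sample_rate_Hz=sample_rate_Hz,
        buffer=buffer,
        protocol=proto,
        trace_id=trace_id,
    )
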