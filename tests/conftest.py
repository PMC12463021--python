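import numpy as np
import pytest

from algalogic import ChannelParams, TimeSeries, generate_channel


@pytest.fixture
def sine_500s() -> TimeSeries:
    """Undamped 80 mV sinusoid with a 500 s period, 5000 s at 1 Hz."""
    params = ChannelParams(label="sine", amplitude_A=80.0, period_T=500.0,
                           damping_alpha=0.0)
    return generate_channel(params, duration=5000.0, rate=1.0)


@pytest.fixture
def zero_series() -> TimeSeries:
    return TimeSeries(t0=0.0, rate=1.0, values=np.zeros(1000), label="flat")
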