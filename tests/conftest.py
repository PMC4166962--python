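import numpy as np
import pytest

from lifspec import NeuronParams, SpikeTrain, SynapseConfig


@pytest.fixture
def neuron() -> NeuronParams:
    """Standard membrane constants: tau=20 ms, v_T=20 mV, v_R=10 mV,
    tau_ref=2 ms, dt=0.1 ms."""
    return NeuronParams()


@pytest.fixture
def neuron_reset0() -> NeuronParams:
    return NeuronParams(v_reset=0.0)


@pytest.fixture
def balanced_syn() -> SynapseConfig:
    """Balanced standard synapses: C_E=1000, gamma=0.25, J=0.1 mV, g=4."""
    return SynapseConfig()


def poisson_trains(rate_hz: float, duration_ms: float, n: int,
                   rng: np.random.Generator) -> list[SpikeTrain]:
    """Homogeneous Poisson spike trains (uniform order statistics)."""
    trains = []
    for i in range(n):
        count = rng.poisson(rate_hz * duration_ms / 1000.0)
        times = np.sort(rng.uniform(0.0, duration_ms, count))
        times = np.unique(times)  # strict ordering; collisions have measure ~0
        trains.append(SpikeTrain(times=times, duration=duration_ms, trial_id=i))
    return trains


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
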