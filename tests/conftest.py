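import numpy as np
import pytest

from echovol import EchoParams, synthesize_echo
from echovol.experiments import BENCHMARK_ECHO, STUDY_ECHO


@pytest.fixture(scope="session")
def study_echo_params() -> EchoParams:
    """The simulation echo theta = (2, 0.4, 15 us, 1 MHz, 0)."""
    return STUDY_ECHO


@pytest.fixture(scope="session")
def study_echo_signal(study_echo_params):
    """500 samples at 10 MHz of the simulation echo."""
    return synthesize_echo(study_echo_params, 500, 10.0)


@pytest.fixture(scope="session")
def benchmark_echo_signal():
    """The denoising-benchmark echo (1 MHz / 200 kHz / N=500 / fs=10 MHz)."""
    return synthesize_echo(BENCHMARK_ECHO, 500, 10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
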