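import numpy as np
import pytest

from trflab import LagSpec
from trflab.synthetic import KernelSpec, make_kernel, make_stimulus, simulate_response

FS = 128.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_system(rng):
    """A well-conditioned 50x8 regression problem with 2 outputs."""
    X = rng.standard_normal((50, 8))
    Y = rng.standard_normal((50, 2))
    return X, Y


@pytest.fixture
def noise_free_trial():
    """White stimulus convolved with a known kernel, no noise, 4 channels."""
    kernel = make_kernel(KernelSpec(), 1, 4, FS, seed=7)
    stimulus = make_stimulus("white", 4000, FS, seed=8)
    response = simulate_response(stimulus, kernel, np.inf, seed=9)
    return stimulus, response, kernel


@pytest.fixture
def noisy_trials():
    """Three 20-s white-stimulus trials at 0 dB SNR sharing one kernel."""
    kernel = make_kernel(KernelSpec(), 1, 4, FS, seed=17)
    stimuli, responses = [], []
    for j in range(3):
        s = make_stimulus("white", int(20 * FS), FS, seed=20 + j)
        stimuli.append(s)
        responses.append(simulate_response(s, kernel, 0.0, seed=30 + j))
    return stimuli, responses, kernel


@pytest.fixture
def lagspec():
    return LagSpec(-50.0, 350.0, FS)
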