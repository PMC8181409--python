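import logging

import numpy as np
import pytest

from hopfnet import run_experiment

logging.getLogger("hopfnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fig11_report():
    """Full real-mode Fourier-decomposition training run (expensive; shared
    by the reservoir tests and the acceptance checks)."""
    return run_experiment("fig11")


@pytest.fixture(scope="session")
def fig12_report():
    """Full complex-mode Fourier-decomposition training run."""
    return run_experiment("fig12")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
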