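import numpy as np
import pytest

from hostresponse import (Dataset, Measurement, default_true_params, generate,
                          paper_design)


@pytest.fixture(scope="session")
def truth():
    return default_true_params()


@pytest.fixture(scope="session")
def design5():
    return paper_design(5)


@pytest.fixture(scope="session")
def noisefree_dataset(truth, design5):
    return generate(truth, design5, sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_dataset(truth, design5):
    return generate(truth, design5, seed=42)


@pytest.fixture()
def tiny_dataset():
    """Four observations, two dose cells at 24 h, two replicates each."""
    return Dataset([
        Measurement("invasion", 0.0, 24.0, 8.1, 1),
        Measurement("invasion", 0.0, 24.0, 7.9, 2),
        Measurement("invasion", 25.0, 24.0, 24.0, 1),
        Measurement("invasion", 25.0, 24.0, 26.0, 2),
    ])


@pytest.fixture(scope="session")
def time_grid():
    return np.linspace(0.0, 200.0, 201)
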