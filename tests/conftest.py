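import numpy as np
import pytest

from kernogram import (
    KernelSpec,
    SynthConfig,
    fit_svm,
    generate,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def circles():
    """Small two-circles problem (fast; still separable by radius)."""
    return generate(SynthConfig("two_circles", n_total=300, seed=5))


@pytest.fixture(scope="session")
def circles_full():
    """Full-size two-circles problem (n=1000, 500/500)."""
    return generate(SynthConfig("two_circles", n_total=1000, seed=5))


@pytest.fixture(scope="session")
def rbf_circle_model(circles):
    train, _ = circles
    return fit_svm(train, KernelSpec("rbf", gamma=0.5), 10.0)


@pytest.fixture(scope="session")
def poly2_circle_model(circles):
    train, _ = circles
    return fit_svm(train, KernelSpec("polynomial", degree_delta=2), 0.01)
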