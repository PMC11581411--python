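import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_exact_k_sem(alpha=0.3, A=((0.2, 0.1), (0.1, 0.3)), c=(0.2, 0.6)):
    """The two-instrument, two-exposure diagram used throughout the tests."""
    from mvmrset import sem

    return sem.build_mvmr_sem([[1.0, alpha], [alpha, 1.0]], A, c)


@pytest.fixture
def exact_k_sem():
    return make_exact_k_sem()
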