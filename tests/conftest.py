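import numpy as np
import pytest

from schemarsa import build_stimulus_set


@pytest.fixture(scope="session")
def default_set():
    """The 36-condition design: 6 scenes x (3 vertical x 2 horizontal)."""
    return build_stimulus_set()


@pytest.fixture(scope="session")
def small_set():
    """A reduced 8-condition design (2 scenes x 2 x 2) for fast pipelines."""
    return build_stimulus_set(1, 2, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
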