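import numpy as np
import pytest

from neurocardiac import CohortSpec, synth


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """1 F + 1 M, 2 runs x 6 trials, full three-phase design."""
    return CohortSpec(n_female=1, n_male=1, runs_per_phase=2,
                      trials_per_run=6, seed=11)


@pytest.fixture(scope="session")
def tiny_events(tiny_spec):
    return synth.generate_events(tiny_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
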