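import numpy as np
import pytest

from dyndesign.synthetic import (build_canonical_model, emit_observables,
                                 expand_to_microstates, simulate_dtrajs)


@pytest.fixture(scope="session")
def wt_macro_model():
    return build_canonical_model("WT")


@pytest.fixture(scope="session")
def d66a_macro_model():
    return build_canonical_model("D66A")


@pytest.fixture(scope="session")
def wt_micro_model(wt_macro_model):
    return expand_to_microstates(wt_macro_model, 20)


@pytest.fixture(scope="session")
def wt_traj_small(wt_micro_model):
    """Light WT trajectory set for unit tests (20 x 4000 steps)."""
    return simulate_dtrajs(wt_micro_model, 20, 4000, seed=1234)


@pytest.fixture(scope="session")
def wt_observables_small(wt_traj_small, wt_micro_model):
    return emit_observables(wt_traj_small, wt_micro_model, seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(2468)
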