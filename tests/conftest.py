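import numpy as np
import pytest

from eisosim import build_config, init_lattice


@pytest.fixture(scope="session")
def default_config():
    return build_config()


@pytest.fixture()
def small_config():
    """A small lattice that keeps brute-force oracles cheap."""
    return build_config(Lx=11, Ly=13, N=3, bar_rows=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def perturb_state(state, rng, scale=0.05, config=None):
    """Random feasible-ish perturbation of a lattice state (z kept <= 0,
    frozen ring untouched in z)."""
    movable = ~state.frozen_z
    state.x += rng.uniform(-scale, scale, size=state.x.shape)
    dz = rng.uniform(-scale, scale, size=state.z.shape)
    state.z = np.where(movable, np.minimum(state.z + dz, 0.0), state.z)
    return state


@pytest.fixture()
def perturbed_state(small_config, rng):
    return perturb_state(init_lattice(small_config), rng, config=small_config)
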