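import numpy as np
import pytest

from ure import (
    Ensemble,
    ObservableClass,
    ObservableSet,
    make_grid_system,
    make_recovery_fixture,
)


@pytest.fixture
def micro():
    """Two-conformer, one-observable system with closed-form behavior.

    prior (0.5, 0.5); calc column (0, 1); exp 1; sigma 1.  The k-to-weights
    map reduces to a logistic in k/2, so every diagnostic has a hand
    value.
    """
    prior = Ensemble(np.array([0.5, 0.5]))
    obs = ObservableSet(
        labels=("o",),
        obs_class=(ObservableClass.SHIFT,),
        exp_value=[1.0],
        sigma=[1.0],
        calc_matrix=[[0.0], [1.0]],
    )
    return prior, obs


@pytest.fixture(scope="session")
def grid_fixture():
    """Seeded 36x36 dihedral-grid recovery fixture with 12 observables."""
    grid = make_grid_system(seed=1)
    return make_recovery_fixture(grid, 2.0, noise_sd=0.2, seed=1)


@pytest.fixture(scope="session")
def small_grid_fixture():
    """Smaller 12x12 grid fixture for optimizer-heavy tests."""
    grid = make_grid_system(phi_bins=12, psi_bins=12, n_obs=6, seed=7)
    return make_recovery_fixture(grid, 2.0, noise_sd=0.2, seed=7)
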