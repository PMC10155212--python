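import numpy as np
import pytest

from mabcluster import mc
from mabcluster.geometry import UnitSystem, build_y_geometry, concentration_to_number_density


@pytest.fixture(scope="session")
def y_geometry():
    return build_y_geometry()

@pytest.fixture(scope="session")
def units():
    return UnitSystem()


@pytest.fixture(scope="session")
def small_trajectory():
    """One short desk-scale replica at the working concentration.

    Shared across MC tests to amortize the simulation cost; big enough to
    contain bonded clusters but far below production statistics.
    """
    cfg = mc.MCConfig(
        N=40,
        rho=concentration_to_number_density(61.7),
        T=0.11,
        sweeps_equil=4000,
        sweeps_prod=4000,
        sample_every=400,
        seed=5,
        n_replicas=1,
    )
    return mc.simulate(cfg), cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
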