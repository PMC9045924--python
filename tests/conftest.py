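import numpy as np
import pytest

from desmoke.forward import Airlight, generate_optical_depth, generate_scene

# Table 1 media: (diameter µm, density µm⁻³, µs cm⁻¹, g)
SMALL_PARTICLE = {"diameter": 0.2, "density": 2e-3, "mu_s": 0.1737,
                  "g": 0.2052}
LARGE_PARTICLE = {"diameter": 6.0, "density": 1e-6, "mu_s": 0.6230,
                  "g": 0.7324}
WAVELENGTH = 0.630
# printed index is 1.57+0.4277i; the table values follow the real part
# (see README, "Refractive-index convention")
PARTICLE_INDEX_REAL = 1.57 + 0.0j
PARTICLE_INDEX_FULL = 1.57 + 0.4277j
MU_A = 0.0100


@pytest.fixture(scope="session")
def mie_small():
    from desmoke.mie import compute_mie
    return compute_mie(SMALL_PARTICLE["diameter"], WAVELENGTH,
                       PARTICLE_INDEX_REAL, 1.0, 1801)


@pytest.fixture(scope="session")
def mie_large():
    from desmoke.mie import compute_mie
    return compute_mie(LARGE_PARTICLE["diameter"], WAVELENGTH,
                       PARTICLE_INDEX_REAL, 1.0, 1801)


@pytest.fixture(scope="session")
def airlight_polarized():
    """Fully polarized smoke ambiance (cross component zero): the regime in
    which the polarization-difference inversion is exact."""
    return Airlight([0.62, 0.58, 0.55], [0.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def airlight_partial():
    """Partially polarized ambiance, the realistic regime."""
    return Airlight([0.62, 0.58, 0.55], [0.124, 0.116, 0.110])


@pytest.fixture(scope="session")
def checker_depolarized():
    return generate_scene("checker", 128, 128, 0.0, rng_seed=1)


@pytest.fixture(scope="session")
def checker_polarized():
    return generate_scene("checker", 128, 128, 0.3, rng_seed=1)


@pytest.fixture(scope="session")
def uniform_u1():
    return generate_optical_depth("uniform", 1.0, 128, 128)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
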