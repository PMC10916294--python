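import numpy as np
import pytest

from tham.databank import build_bank
from tham.density import make_fixture
from tham.quadrature import angular_grid, atomic_grid, mura_knowles_radial


@pytest.fixture(scope="session")
def water_spec():
    return make_fixture("water-like", seed=0)


@pytest.fixture(scope="session")
def all_fixture_specs():
    from tham.density import FIXTURE_NAMES
    return {name: make_fixture(name, seed=0) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def water_bank(water_spec):
    """Databank built from the water-like fixture alone."""
    return build_bank([water_spec])


@pytest.fixture(scope="session")
def default_grid():
    """75-point radial x 590-point angular product grid (scale 5 A)."""
    return atomic_grid(mura_knowles_radial(75, 5.0), angular_grid(590))


def random_rotation(rng):
    """Haar-ish random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_spd(rng, lo=0.005, hi=0.08):
    """Random SPD tensor with eigenvalues in [lo, hi] A^2."""
    r = random_rotation(rng)
    return r @ np.diag(rng.uniform(lo, hi, 3)) @ r.T
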