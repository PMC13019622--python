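import json
from importlib.resources import files

import numpy as np
import pytest
import scipy.linalg

from nofpair.integrals import (
    IntegralSet,
    OrbitalRotation,
    build_hubbard,
    read_fcidump,
    symmetrize_eri,
    transform_basis,
)
from nofpair.pairing import build_scheme

# closed-form singlet ground energy of the two-site model at half filling
DIMER_E_FCI = (4.0 - np.sqrt(4.0**2 + 16.0)) / 2.0  # -0.8284271247...


def dimer_natural_occupancies(u=4.0, t=1.0):
    """cos^2/sin^2 of the 2x2 singlet mixing angle, tan(2θ) = U/(4t):
    the doubly occupied configurations |g²>, |u²> sit 4t apart and couple
    through the off-diagonal element U/2."""
    theta = 0.5 * np.arctan2(u, 4.0 * t)
    return np.cos(theta) ** 2, np.sin(theta) ** 2


@pytest.fixture
def dimer():
    return build_hubbard(2, 1.0, 4.0, 2)


@pytest.fixture
def dimer_mo(dimer):
    """Two-site model rotated to the bonding/antibonding basis."""
    _, c = scipy.linalg.eigh(dimer.h_one)
    return transform_basis(dimer, OrbitalRotation(c))


@pytest.fixture
def dimer_scheme():
    return build_scheme(2, 1, 2, "max")


@pytest.fixture
def hubbard4():
    return build_hubbard(4, 1.0, 4.0, 4)


@pytest.fixture
def scheme4():
    return build_scheme(4, 1, 4, "max")


def random_integral_set(rng, n_basis, n_electrons=4, scale=0.3):
    """Random real symmetric Hamiltonian data (8-fold symmetric eri)."""
    h = rng.normal(size=(n_basis, n_basis))
    h = 0.5 * (h + h.T)
    eri = symmetrize_eri(rng.normal(size=(n_basis,) * 4)) * scale
    return IntegralSet(
        n_basis=n_basis,
        n_electrons=n_electrons,
        ms2=0,
        core_constant=0.0,
        h_one=h,
        eri=eri,
    )


@pytest.fixture
def fixture_meta():
    return json.loads((files("nofpair.data") / "fixtures.json").read_text())


def load_fixture(name):
    return read_fcidump(files("nofpair.data") / f"{name}.fcidump")
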