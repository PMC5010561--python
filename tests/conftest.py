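import numpy as np
import pytest

from frexs import MonomerStateSet, ToyMonomerSpec, make_dimer_geometry, make_toy_monomer


def two_level_monomer(core_energy=710.0, dipole=(0.1, 0.0, 0.0)):
    """Ground + one core state with a single (possibly complex) dipole."""
    d = np.zeros((2, 2, 3), dtype=complex)
    d[0, 1] = np.asarray(dipole, dtype=complex)
    d[1, 0] = np.conj(d[0, 1])
    return MonomerStateSet(
        energies=[0.0, core_energy],
        spin_multiplicity=["mixed", "mixed"],
        manifold=["ground", "core"],
        dipoles=d,
    ).validate()


def three_state_monomer(seed=0, e_v=2.0, e_c=710.0, scales=(0.05, 0.02, 0.005)):
    """g/v/c toy with every pairwise transition dipole nonzero (complex)."""
    rng = np.random.default_rng(seed)
    gc, vc, gv = scales
    d = np.zeros((3, 3, 3), dtype=complex)
    for (a, b), s in (((0, 1), gv), ((0, 2), gc), ((1, 2), vc)):
        d[a, b] = s * rng.uniform(0.5, 1, 3) * np.exp(1j * rng.uniform(0, 2 * np.pi, 3))
        d[b, a] = np.conj(d[a, b])
    return MonomerStateSet(
        energies=[0.0, e_v, e_c],
        spin_multiplicity=["mixed"] * 3,
        manifold=["ground", "valence", "core"],
        dipoles=d,
    ).validate()


@pytest.fixture
def small_toy_pair():
    """Two distinct seeded toy monomers, <= 6 states each."""
    spec = ToyMonomerSpec(n_ground=2, n_valence=2, n_core=2, seed=101)
    m1 = make_toy_monomer(spec)
    m2 = make_toy_monomer(ToyMonomerSpec(n_ground=2, n_valence=2, n_core=2, seed=202))
    return m1, m2


@pytest.fixture
def geometry():
    return make_dimer_geometry(7.0, 0.0)
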