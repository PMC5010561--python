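"""Seeded synthetic monomers emulating the manifold layout of an L-edge
absorber (hemin-like): a small near-degenerate ground Kramers manifold, a
valence manifold reaching a few eV, and a dense core-excited manifold around
the metal L3/L2 edges, with dipole-allowed ground->core transitions much
stronger than valence->core and ground->valence ones.

Energies are drawn uniformly within each manifold's range — tests need
controlled structure, not multiplet realism — and dipole phases are uniform
on the unit circle so that complex (spin-orbit) arithmetic is genuinely
exercised.  Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .hamiltonian import DimerGeometry
from .monomer import CORE, GROUND, VALENCE, MonomerStateSet


@dataclass(frozen=True)
class ToyMonomerSpec:
    """Recipe for a synthetic monomer.

    Ground states come in Kramers doublets separated by ``ground_splitting``
    (the degeneracy-lifting of the ground multiplet by spin-orbit coupling;
    the doublet partners themselves are exactly degenerate).  Dipole block
    scales (a.u.) set the magnitude hierarchy: ground->core strongest (the
    dipole-allowed 2p->3d channel), valence->core weaker, ground->valence
    weakest.
    """

    n_ground: int = 2
    ground_splitting: float = 0.005
    n_valence: int = 10
    valence_span: float = 7.3
    n_core: int = 10
    core_range: tuple = (710.6, 732.9)
    dipole_scale_gc: float = 0.05
    dipole_scale_vc: float = 0.02
    dipole_scale_gv: float = 0.005
    dipole_scale_within: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ground, self.n_valence, self.n_core) < 0 or self.n_ground == 0:
            raise ValueError("state counts must be non-negative, with n_ground >= 1")
        if self.core_range[0] >= self.core_range[1] and self.n_core > 1:
            raise ValueError("core_range must be ordered")
        if min(
            self.dipole_scale_gc,
            self.dipole_scale_vc,
            self.dipole_scale_gv,
            self.dipole_scale_within,
        ) < 0:
            raise ValueError("dipole scales must be non-negative")
        ground_top = ((self.n_ground - 1) // 2) * self.ground_splitting
        if self.n_valence and ground_top >= 0.5:
            raise ValueError("ground manifold overlaps the valence range")
        if self.n_valence and self.valence_span <= 0.5:
            raise ValueError("valence_span too small for the valence draw window")
        if self.n_core and self.n_valence and self.core_range[0] <= self.valence_span:
            raise ValueError("core and valence manifold ranges overlap")


def _block_scale(spec: ToyMonomerSpec, m_a: str, m_b: str) -> float:
    pair = frozenset((m_a, m_b))
    if pair == frozenset((GROUND, CORE)):
        return spec.dipole_scale_gc
    if pair == frozenset((VALENCE, CORE)):
        return spec.dipole_scale_vc
    if pair == frozenset((GROUND, VALENCE)):
        return spec.dipole_scale_gv
    return spec.dipole_scale_within  # within-manifold (gg / vv / cc)


def make_toy_monomer(spec: ToyMonomerSpec) -> MonomerStateSet:
    """Generate a validated :class:`MonomerStateSet` from a spec, seeded."""
    rng = np.random.default_rng(spec.seed)
    ground = np.array(
        [(k // 2) * spec.ground_splitting for k in range(spec.n_ground)]
    )
    valence = (
        np.sort(rng.uniform(0.5, spec.valence_span, spec.n_valence))
        if spec.n_valence
        else np.empty(0)
    )
    core = (
        np.sort(rng.uniform(*spec.core_range, spec.n_core))
        if spec.n_core
        else np.empty(0)
    )
    energies = np.concatenate([ground, valence, core])
    manifold = (
        [GROUND] * spec.n_ground + [VALENCE] * spec.n_valence + [CORE] * spec.n_core
    )
    n = energies.size

    d = np.zeros((n, n, 3), dtype=complex)
    for a in range(n):
        for b in range(a + 1, n):
            scale = _block_scale(spec, manifold[a], manifold[b])
            if scale == 0:
                continue
            mag = rng.uniform(0.5, 1.0, 3) * scale
            phase = rng.uniform(0.0, 2 * np.pi, 3)
            d[a, b] = mag * np.exp(1j * phase)
            d[b, a] = np.conj(d[a, b])
    # diagonal (static) dipoles must be real by Hermiticity
    if spec.dipole_scale_within:
        for a in range(n):
            d[a, a] = rng.uniform(-1.0, 1.0, 3) * spec.dipole_scale_within

    return MonomerStateSet(
        energies=energies,
        spin_multiplicity=["mixed"] * n,
        manifold=manifold,
        dipoles=d,
    ).validate()


PRESETS = {
    # closed-form toy: one state per manifold, deterministic phases
    "minimal-3-state": ToyMonomerSpec(
        n_ground=1,
        n_valence=1,
        n_core=1,
        ground_splitting=0.0,
        seed=7,
    ),
    # desk-scale hemin-like dimer fixture
    "hemin-like-small": ToyMonomerSpec(
        n_ground=2, n_valence=12, n_core=20, seed=11
    ),
    # full published state counts: 6 ground + 96 valence + 690 core = 792
    "hemin-like-full-counts": ToyMonomerSpec(
        n_ground=6, n_valence=96, n_core=690, seed=13
    ),
}


def make_preset(name: str, seed: int | None = None) -> MonomerStateSet:
    """Instantiate a registered preset, optionally re-seeded."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    spec = PRESETS[name]
    if seed is not None:
        spec = replace(spec, seed=seed)
    return make_toy_monomer(spec)


def make_dimer_geometry(distance: float = 7.0, rotation_deg: float = 0.0) -> DimerGeometry:
    """Dimer geometry with the separation along the lab z axis.

    ``distance`` in atomic units (7 a.u. is the representative stacking
    distance for hemin dimers); ``rotation_deg`` rotates monomer 2 about the
    separation axis (0/90/180 degrees map the relative orientations of the
    propionic-acid side groups).
    """
    if not distance > 0:
        raise ValueError("distance must be positive")
    return DimerGeometry(np.array([0.0, 0.0, float(distance)]), rotation_deg)
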