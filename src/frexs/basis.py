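"""Exciton bases for a dimer: one-particle (OPA) and two-particle (TPA)
product configurations, plus core-state energy windowing.

Configurations are Hartree products |A1 B2> of monomer eigenstates.  The OPA
basis keeps the ground product and single excitations; the TPA basis is the
full product space and is exact for a dimer.  Rule (c) pre-selects core
states inside an energy window of half-width ``multiplier * sigma`` around
the excitation-pulse center, which is what makes the large-manifold problem
tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .monomer import CORE, GROUND, VALENCE, MonomerStateSet

OPA = "OPA"
TPA = "TPA"


class WindowWarning(UserWarning):
    """The core-state energy window selected nothing."""


@dataclass(frozen=True)
class ExcitonConfiguration:
    """Product configuration |state_1 on monomer 1, state_2 on monomer 2>."""

    state_1: int
    state_2: int
    zeroth_order_energy: float  # eV; E1 + E2 exactly


@dataclass
class ExcitonBasis:
    """Ordered configuration list with construction metadata.

    Ordering is the documented stable sort by
    ``(zeroth_order_energy, state_1, state_2)``.
    """

    configurations: list
    approximation: str
    window: tuple | None = None  # (center eV, half-width eV) on core states

    @property
    def size(self) -> int:
        return len(self.configurations)

    def pairs(self) -> list:
        return [(c.state_1, c.state_2) for c in self.configurations]

    def zeroth_order_energies(self) -> np.ndarray:
        return np.array([c.zeroth_order_energy for c in self.configurations])


def _core_ok(monomer: MonomerStateSet, idx: int, window) -> bool:
    if window is None or monomer.manifold[idx] != CORE:
        return True
    center, half_width = window
    return abs(monomer.energies[idx] - center) <= half_width


def build_basis(
    m1: MonomerStateSet,
    m2: MonomerStateSet,
    approximation: str = TPA,
    window=None,
) -> ExcitonBasis:
    """Construct the OPA or TPA exciton basis for a dimer.

    OPA: all ground-ground products, plus single excitations |a1 g2> and
    |g1 a2> with ``a`` ranging over valence and core states and ``g`` over the
    ground manifold.  TPA: the full product space of the two monomers' states.
    With a ``window = (center, half_width)`` every configuration containing a
    core state outside ``[center - half_width, center + half_width]`` is
    dropped (closed interval, applied per core state).
    """
    if approximation not in (OPA, TPA):
        raise ValueError(f"unknown approximation {approximation!r}; use 'OPA' or 'TPA'")
    if window is not None:
        center, half_width = window
        if not half_width > 0:
            raise ValueError("window half-width must be positive")

    pairs: set = set()
    if approximation == TPA:
        pairs.update(
            (i, j) for i in range(m1.n_states) for j in range(m2.n_states)
        )
    else:
        g1 = m1.states_in(GROUND)
        g2 = m2.states_in(GROUND)
        exc1 = [i for i in range(m1.n_states) if m1.manifold[i] != GROUND]
        exc2 = [j for j in range(m2.n_states) if m2.manifold[j] != GROUND]
        pairs.update((int(i), int(j)) for i in g1 for j in g2)
        pairs.update((int(a), int(g)) for a in exc1 for g in g2)
        pairs.update((int(g), int(a)) for g in g1 for a in exc2)

    if window is not None:
        pairs = {
            (i, j)
            for (i, j) in pairs
            if _core_ok(m1, i, window) and _core_ok(m2, j, window)
        }
    if not pairs:
        raise ValueError("resulting exciton basis is empty")

    configs = [
        ExcitonConfiguration(i, j, float(m1.energies[i] + m2.energies[j]))
        for (i, j) in pairs
    ]
    configs.sort(key=lambda c: (c.zeroth_order_energy, c.state_1, c.state_2))
    return ExcitonBasis(configs, approximation, window)


def count_basis(n_val: int, n_core: int, approximation: str) -> int:
    """Rank of the dimer Hamiltonian block under the ledger counting convention.

    ``n_val`` counts the valence-manifold states *including* the ground
    multiplet (the convention behind the quoted manifold sizes), ``n_core``
    the core-excited states.

    TPA (the RIXS bookkeeping): one core excitation on either monomer paired
    with any valence-manifold state on the other, plus the singly
    valence-excited configurations on either monomer —
    ``2 * n_val * n_core + 2 * n_val``.  OPA:
    ``1 + 2 * (n_val - 1) + 2 * n_core``.  Note the TPA ledger is a multiset
    count (the all-ground product appears in both single-excitation terms);
    set-semantics enumeration is provided by :func:`build_basis`.
    """
    if n_val < 1:
        raise ValueError("n_val must be >= 1 (the ground state is counted within it)")
    if n_core < 0:
        raise ValueError("n_core must be >= 0")
    if approximation == TPA:
        return 2 * n_val * n_core + 2 * n_val
    if approximation == OPA:
        return 1 + 2 * (n_val - 1) + 2 * n_core
    raise ValueError(f"unknown approximation {approximation!r}")


def select_core_window(core_energies, center: float, sigma: float, multiplier: float = 5.0):
    """Pre-select core states inside ``|E - center| <= multiplier * sigma``.

    ``sigma`` is the Gaussian width of the excitation pulse; the default
    multiplier of 5 gives the ±5σ window (±1.25 eV for a 0.25 eV pulse).
    Returns ``(kept_indices, half_width)``; warns when nothing survives.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if not multiplier > 0:
        raise ValueError("multiplier must be positive")
    core_energies = np.asarray(core_energies, dtype=float)
    half_width = multiplier * sigma
    kept = np.nonzero(np.abs(core_energies - center) <= half_width)[0]
    if kept.size == 0:
        warnings.warn(
            f"core-state window [{center - half_width}, {center + half_width}] eV "
            "selected no states",
            WindowWarning,
            stacklevel=2,
        )
    return kept, half_width
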