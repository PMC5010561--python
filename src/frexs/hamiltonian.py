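"""Aggregate Hamiltonian of a dimer in the point-dipole approximation.

The diagonal holds zeroth-order configuration energies E_A1 + E_B2; the
off-diagonal couples the monomer transitions A1->D1 and B2->C2 through the
dipole-dipole interaction

    J = dA.dB / |X|^3 - 3 (X.dA)(X.dB) / |X|^5        (atomic units)

converted to eV before entering the matrix.  Complex (spin-orbit coupled)
transition dipoles are contracted bilinearly — no conjugation inside J — and
Hermiticity of H is inherited from the Hermiticity of the monomer dipole
matrices.

Coupling-neglect rules mirror the physical hierarchy of L-edge transitions:
(a) couplings of g<->v transitions with g<->v and with v<->c transitions are
dropped, (b) static dipoles (diagonal dipole elements) do not couple to
anything.  Both are individually switchable through :class:`RuleFlags`, and
disabling everything reproduces the exact product-space dimer Hamiltonian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .basis import ExcitonBasis
from .monomer import HARTREE_EV, MonomerStateSet

DEFAULT_MAX_DENSE_DIM = 4000

_CLASS_INITIAL = {"ground": "g", "valence": "v", "core": "c"}


def transition_class(manifold_a: str, manifold_b: str) -> str:
    """Canonical label of a monomer transition by manifold pair, e.g. 'gc'."""
    a, b = _CLASS_INITIAL[manifold_a], _CLASS_INITIAL[manifold_b]
    order = {"g": 0, "v": 1, "c": 2}
    return a + b if order[a] <= order[b] else b + a


def _pair_key(class_1: str, class_2: str) -> tuple:
    return tuple(sorted((class_1, class_2)))


@dataclass(frozen=True)
class RuleFlags:
    """Which Coulomb couplings enter the aggregate Hamiltonian.

    ``neglect_static`` is rule (b): any element where one monomer keeps its
    state (a static-dipole factor) is zeroed, including the static-static
    diagonal shift.  ``neglected_class_pairs`` is rule (a): unordered pairs of
    transition classes set to zero; the default drops (gv, gv) and (gv, vc).
    ``couplings_enabled = False`` zeroes every off-diagonal element (the
    uncoupled-dimer limit).
    """

    couplings_enabled: bool = True
    neglect_static: bool = True
    neglected_class_pairs: frozenset = frozenset({("gv", "gv"), ("gv", "vc")})

    @classmethod
    def all_off(cls) -> "RuleFlags":
        """No neglect rules at all: the exact product-space Hamiltonian."""
        return cls(neglect_static=False, neglected_class_pairs=frozenset())

    @classmethod
    def uncoupled(cls) -> "RuleFlags":
        return cls(couplings_enabled=False)


@dataclass
class DimerGeometry:
    """Center-to-center vector X12 (a.u.) and rotation of monomer 2.

    ``rotation_deg`` is an active rotation of monomer 2 about the separation
    axis; in the point-dipole limit geometry enters only through X12 and the
    rotated dipole orientations.
    """

    separation: np.ndarray
    rotation_deg: float = 0.0

    def __post_init__(self):
        self.separation = np.asarray(self.separation, dtype=float)
        if self.separation.shape != (3,):
            raise ValueError("separation must be a 3-vector")
        if np.linalg.norm(self.separation) == 0:
            raise ValueError("monomer separation must be nonzero")

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.separation))

    def rotation_matrix(self) -> np.ndarray:
        axis = self.separation / self.distance
        return Rotation.from_rotvec(np.deg2rad(self.rotation_deg) * axis).as_matrix()


def coupling_tensor(X) -> np.ndarray:
    """Geometric kernel T with J = dA . T . dB, in atomic units.

    ``T = I/R^3 - 3 X X^T / R^5`` for center-to-center vector X.
    """
    X = np.asarray(X, dtype=float)
    R = np.linalg.norm(X)
    if R == 0:
        raise ValueError("zero separation between dipoles")
    return np.eye(3) / R**3 - 3.0 * np.outer(X, X) / R**5


def dipole_coupling(dA, dB, X) -> complex:
    """Point-dipole interaction energy of two (complex) transition dipoles.

    Bilinear in both dipoles (no complex conjugation); atomic units in,
    hartree out.
    """
    dA = np.asarray(dA, dtype=complex)
    dB = np.asarray(dB, dtype=complex)
    return complex(dA @ coupling_tensor(X) @ dB)


@dataclass
class AggregateHamiltonian:
    """Hermitian matrix over an :class:`ExcitonBasis`, in eV.

    Carries the lab-frame monomer dipole matrices used for its assembly so
    that eigenstate transition dipoles can be formed consistently.
    """

    matrix: np.ndarray
    basis: ExcitonBasis
    d1_lab: np.ndarray
    d2_lab: np.ndarray
    rules: RuleFlags = field(default_factory=RuleFlags)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def zeroth_order_energies(self) -> np.ndarray:
        return self.basis.zeroth_order_energies()


@dataclass
class EigenSystem:
    """Eigenvalues (eV, ascending), eigenvectors, and transition dipoles
    between eigenstates (a.u.)."""

    energies: np.ndarray
    vectors: np.ndarray  # columns are eigenstates in the basis
    dipoles: np.ndarray  # (N, N, 3) complex, <p|d|q>


def assemble_hamiltonian(
    basis: ExcitonBasis,
    m1: MonomerStateSet,
    m2: MonomerStateSet,
    geometry: DimerGeometry,
    rules: RuleFlags = RuleFlags(),
    max_dim: int = DEFAULT_MAX_DENSE_DIM,
) -> AggregateHamiltonian:
    """Assemble the dimer Hamiltonian over ``basis`` under the given rules."""
    n = basis.size
    if n > max_dim:
        raise ValueError(
            f"basis size {n} exceeds the dense cap {max_dim}; apply a core-state "
            "energy window to reduce the rank"
        )
    for (i, j) in basis.pairs():
        if not (0 <= i < m1.n_states and 0 <= j < m2.n_states):
            raise ValueError("basis indices do not match the given monomers")

    d1 = m1.lab_dipoles()
    R = geometry.rotation_matrix()
    d2 = np.einsum("ab,ijb->ija", R, m2.lab_dipoles())
    T = coupling_tensor(geometry.separation) * HARTREE_EV  # J straight in eV

    cls1 = [transition_class(m1.manifold[a], m1.manifold[b])
            for a in range(m1.n_states) for b in range(m1.n_states)]
    cls1 = np.array(cls1, dtype=object).reshape(m1.n_states, m1.n_states)
    cls2 = [transition_class(m2.manifold[a], m2.manifold[b])
            for a in range(m2.n_states) for b in range(m2.n_states)]
    cls2 = np.array(cls2, dtype=object).reshape(m2.n_states, m2.n_states)

    pairs = basis.pairs()
    H = np.zeros((n, n), dtype=complex)
    np.fill_diagonal(H, basis.zeroth_order_energies())

    neglected = rules.neglected_class_pairs
    for p, (A, B) in enumerate(pairs):
        for q in range(p, n):
            D, C = pairs[q]
            if not rules.couplings_enabled:
                break
            static_1 = A == D
            static_2 = B == C
            if rules.neglect_static and (static_1 or static_2):
                continue
            if _pair_key(cls1[A, D], cls2[B, C]) in neglected:
                continue
            J = d1[A, D] @ T @ d2[B, C]
            if p == q:
                H[p, p] += J.real  # static-static shift (rules off only)
            else:
                H[p, q] += J
                H[q, p] += np.conj(J)

    return AggregateHamiltonian(H, basis, d1, d2, rules)


def _dipole_operator(agg: AggregateHamiltonian) -> np.ndarray:
    """Configuration-basis matrix of the total dipole operator.

    A one-electron operator changes at most one monomer's state:
    <A1 B2| d |D1 C2> = d1[A,D] δ_BC + d2[B,C] δ_AD.
    """
    pairs = agg.basis.pairs()
    n = len(pairs)
    D = np.zeros((n, n, 3), dtype=complex)
    for p, (A, B) in enumerate(pairs):
        for q, (Dq, C) in enumerate(pairs):
            if B == C:
                D[p, q] += agg.d1_lab[A, Dq]
            if A == Dq:
                D[p, q] += agg.d2_lab[B, C]
    return D


def diagonalize(agg: AggregateHamiltonian, hermiticity_tol: float = 1e-8) -> EigenSystem:
    """Diagonalize and transform transition dipoles to the eigenbasis."""
    H = agg.matrix
    dev = np.abs(H - H.conj().T).max()
    if dev > hermiticity_tol:
        raise ValueError(f"Hamiltonian not Hermitian: max deviation {dev:.3e} eV")
    vals, U = np.linalg.eigh(H)
    D = _dipole_operator(agg)
    dip = np.einsum("ip,ijk,jq->pqk", U.conj(), D, U, optimize=True)
    return EigenSystem(vals, U, dip)


def monomer_eigensystem(m: MonomerStateSet) -> EigenSystem:
    """Trivial eigensystem of an isolated monomer (its own eigenstates)."""
    m.validate()
    return EigenSystem(
        energies=m.energies.copy(),
        vectors=np.eye(m.n_states, dtype=complex),
        dipoles=m.lab_dipoles(),
    )
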