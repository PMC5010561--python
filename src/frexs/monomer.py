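"""Monomer state sets: the exchange format, manifold classification and
spin-orbit state bookkeeping.

A monomer is described by its electronic eigenstates (energies relative to the
lowest state, in eV), a per-state spin-multiplicity label (an integer, or
``"mixed"`` for spin-orbit coupled states), a manifold tag (``ground``,
``valence`` or ``core``) and the complex transition-dipole matrix
``d[A][B] = <A|d|B>`` in atomic units.  Spin-orbit coupling makes the dipoles
genuinely complex; Hermiticity ``d[A][B] = conj(d[B][A])`` is the invariant
that downstream Hamiltonians rely on.

The exchange format is a versioned JSON container.  JSON floats round-trip
bit-exactly through Python's serializer, so ``load(save(x)) == x``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

HARTREE_EV = 27.211386245988
"""Conversion factor, 1 hartree in eV (CODATA)."""

K_B_EV = 8.617333262e-5
"""Boltzmann constant in eV/K."""

GROUND = "ground"
VALENCE = "valence"
CORE = "core"
MANIFOLDS = (GROUND, VALENCE, CORE)

FORMAT_NAME = "frexs-monomer"
FORMAT_VERSION = 1

DEFAULT_HERMITICITY_TOL = 1e-10


class MonomerFormatError(ValueError):
    """The file does not conform to the monomer exchange schema."""


class MonomerValidationError(ValueError):
    """A structurally valid state set violates a physical invariant."""


class ManifoldWarning(UserWarning):
    """Degenerate manifold classification (e.g. no core states found)."""


@dataclass
class MonomerStateSet:
    """Electronic states of one monomer in the lab-independent monomer frame.

    Parameters
    ----------
    energies
        State energies in eV, relative to the monomer ground state
        (``min(energies) == 0``), ascending.
    spin_multiplicity
        Per-state label: integer 2S+1 of a spin-free state, or ``"mixed"``
        for spin-orbit coupled states.
    manifold
        Per-state tag, one of ``ground``/``valence``/``core``.
    dipoles
        Complex array of shape ``(n, n, 3)``; ``dipoles[A, B]`` is the
        transition dipole ``<A|d|B>`` in atomic units.
    center
        Monomer center position, atomic units.
    orientation
        Proper rotation (3x3) taking monomer-frame vectors to the lab frame.
    original_index
        Index map into the pre-sort ordering of the source file, if any.
    """

    energies: np.ndarray
    spin_multiplicity: list
    manifold: list
    dipoles: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    original_index: np.ndarray | None = None
    hermiticity_tol: float = DEFAULT_HERMITICITY_TOL

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=complex)
        self.center = np.asarray(self.center, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.spin_multiplicity = list(self.spin_multiplicity)
        self.manifold = list(self.manifold)

    @property
    def n_states(self) -> int:
        return self.energies.shape[0]

    def states_in(self, manifold: str) -> np.ndarray:
        """Indices of all states carrying the given manifold tag."""
        return np.array(
            [i for i, m in enumerate(self.manifold) if m == manifold], dtype=int
        )

    def lab_dipoles(self) -> np.ndarray:
        """Dipole matrix rotated into the lab frame by ``orientation``."""
        return np.einsum("ab,ijb->ija", self.orientation, self.dipoles)

    def validate(self) -> "MonomerStateSet":
        """Check all invariants; raise :class:`MonomerValidationError` on failure."""
        n = self.n_states
        if n == 0:
            raise MonomerValidationError("state set is empty")
        if len(self.spin_multiplicity) != n or len(self.manifold) != n:
            raise MonomerValidationError(
                "spin_multiplicity/manifold length does not match energies"
            )
        if self.dipoles.shape != (n, n, 3):
            raise MonomerValidationError(
                f"dipoles must have shape ({n}, {n}, 3), got {self.dipoles.shape}"
            )
        for tag in self.manifold:
            if tag not in MANIFOLDS:
                raise MonomerValidationError(f"unknown manifold tag {tag!r}")
        for s in self.spin_multiplicity:
            if s != "mixed" and (not isinstance(s, (int, np.integer)) or s < 1):
                raise MonomerValidationError(f"bad spin multiplicity label {s!r}")
        ground = self.states_in(GROUND)
        if ground.size == 0:
            raise MonomerValidationError("ground manifold is empty")
        if abs(self.energies[ground].min()) > 1e-12:
            raise MonomerValidationError(
                "minimum ground-manifold energy must be 0 (energies are relative)"
            )
        val = self.states_in(VALENCE)
        core = self.states_in(CORE)
        if core.size and val.size:
            if self.energies[core].min() <= self.energies[val].max():
                raise MonomerValidationError(
                    "core-manifold energies must strictly exceed all valence energies"
                )
        dev = np.abs(self.dipoles - np.conj(np.swapaxes(self.dipoles, 0, 1))).max()
        if dev > self.hermiticity_tol:
            raise MonomerValidationError(
                f"dipole matrix not Hermitian: max deviation {dev:.3e} a.u. "
                f"exceeds tolerance {self.hermiticity_tol:.1e}"
            )
        R = self.orientation
        if not (
            np.allclose(R @ R.T, np.eye(3), atol=1e-9)
            and abs(np.linalg.det(R) - 1.0) < 1e-9
        ):
            raise MonomerValidationError("orientation is not a proper rotation")
        return self


def classify_manifolds(
    energies, ground_span: float = 0.01, core_threshold: float = 100.0
) -> list:
    """Tag each state as ground / valence / core from its relative energy.

    States with ``E <= ground_span`` are ground (the span is meant to capture
    near-degenerate Kramers components of the ground multiplet),
    ``ground_span < E < core_threshold`` valence, and ``E >= core_threshold``
    core.  Emits :class:`ManifoldWarning` when no state reaches the core
    threshold.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.size == 0:
        raise MonomerValidationError("cannot classify an empty energy list")
    if not (0 <= ground_span < core_threshold):
        raise ValueError("require 0 <= ground_span < core_threshold")
    if not np.isclose(energies.min(), 0.0, atol=1e-12):
        raise MonomerValidationError(
            "energies must be relative to the ground state (no state at E = 0)"
        )
    tags = []
    for e in energies:
        if e <= ground_span:
            tags.append(GROUND)
        elif e < core_threshold:
            tags.append(VALENCE)
        else:
            tags.append(CORE)
    if CORE not in tags:
        warnings.warn(
            "no state at or above the core threshold; core manifold is empty",
            ManifoldWarning,
            stacklevel=2,
        )
    return tags


@dataclass(frozen=True)
class MultipletCount:
    """Spin-free multiplet bookkeeping: {multiplicity 2S+1: number of states}."""

    counts: tuple

    def __init__(self, counts):
        if isinstance(counts, dict):
            counts = tuple(sorted(counts.items()))
        counts = tuple((int(m), int(c)) for m, c in counts)
        for m, c in counts:
            if m < 1:
                raise ValueError(f"spin multiplicity must be >= 1, got {m}")
            if c < 0:
                raise ValueError(f"state count must be >= 0, got {c}")
        object.__setattr__(self, "counts", counts)


def count_soc_states(counts) -> int:
    """Number of spin-orbit coupled states from a spin-free multiplet table.

    Each spin-free state of multiplicity 2S+1 yields 2S+1 SOC components, so
    the total is ``sum(multiplicity * n_states)``.
    """
    if not isinstance(counts, MultipletCount):
        counts = MultipletCount(counts)
    return sum(m * c for m, c in counts.counts)


def save_monomer(monomer: MonomerStateSet, path) -> None:
    """Write a validated state set to the JSON exchange format."""
    monomer.validate()
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "energies_ev": monomer.energies.tolist(),
        "spin_multiplicity": [
            s if s == "mixed" else int(s) for s in monomer.spin_multiplicity
        ],
        "manifold": list(monomer.manifold),
        "dipoles_re_au": monomer.dipoles.real.tolist(),
        "dipoles_im_au": monomer.dipoles.imag.tolist(),
        "center_au": monomer.center.tolist(),
        "orientation": monomer.orientation.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_monomer(path, hermiticity_tol: float = DEFAULT_HERMITICITY_TOL) -> MonomerStateSet:
    """Read and validate a monomer exchange file.

    Energies are sorted ascending (stable sort); the pre-sort position of each
    state is kept in ``original_index``.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise MonomerFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_NAME:
        raise MonomerFormatError(f"missing or wrong 'format' field (expected {FORMAT_NAME!r})")
    if doc.get("version") != FORMAT_VERSION:
        raise MonomerFormatError(f"unsupported schema version {doc.get('version')!r}")
    required = [
        "energies_ev",
        "spin_multiplicity",
        "manifold",
        "dipoles_re_au",
        "dipoles_im_au",
        "center_au",
        "orientation",
    ]
    for key in required:
        if key not in doc:
            raise MonomerFormatError(f"missing required field {key!r}")
    energies = np.asarray(doc["energies_ev"], dtype=float)
    n = energies.shape[0]
    try:
        re = np.asarray(doc["dipoles_re_au"], dtype=float)
        im = np.asarray(doc["dipoles_im_au"], dtype=float)
    except ValueError as exc:
        raise MonomerFormatError(f"malformed dipole arrays: {exc}") from exc
    for name, arr in (("dipoles_re_au", re), ("dipoles_im_au", im)):
        if arr.shape != (n, n, 3):
            raise MonomerFormatError(
                f"field {name!r}: expected shape ({n},{n},3), got {arr.shape}"
            )
    dip = re + 1j * im
    order = np.argsort(energies, kind="stable")
    monomer = MonomerStateSet(
        energies=energies[order],
        spin_multiplicity=[doc["spin_multiplicity"][i] for i in order],
        manifold=[doc["manifold"][i] for i in order],
        dipoles=dip[np.ix_(order, order)],
        center=np.asarray(doc["center_au"], dtype=float),
        orientation=np.asarray(doc["orientation"], dtype=float),
        original_index=order,
        hermiticity_tol=hermiticity_tol,
    )
    return monomer.validate()
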