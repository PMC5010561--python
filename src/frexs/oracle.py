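"""Brute-force reference implementations, for tests only.

Everything here re-derives its result with naive explicit loops and its own
inline formulas (dipole-dipole kernel, axis-angle rotation, Kramers-
Heisenberg inner sum), sharing only the data types with the production code,
so that agreement between the two paths is a genuine cross-check rather than
a tautology.  Hard size caps raise instead of truncating: the oracle never
approximates.
"""

from __future__ import annotations

import numpy as np

from .basis import ExcitonBasis, ExcitonConfiguration
from .hamiltonian import AggregateHamiltonian, DimerGeometry, EigenSystem, RuleFlags
from .monomer import HARTREE_EV, MonomerStateSet

FULL_PRODUCT_CAP = 2500


def _axis_angle_matrix(axis, angle_deg):
    # Rodrigues' formula, written out
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.sqrt(axis @ axis)
    t = np.deg2rad(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def _naive_coupling(dA, dB, X):
    R = np.sqrt(X @ X)
    if R == 0:
        raise ValueError("zero separation")
    term1 = sum(dA[k] * dB[k] for k in range(3)) / R**3
    term2 = 3.0 * sum(X[k] * dA[k] for k in range(3)) * sum(
        X[k] * dB[k] for k in range(3)
    ) / R**5
    return term1 - term2


def full_product_hamiltonian(
    m1: MonomerStateSet,
    m2: MonomerStateSet,
    geometry: DimerGeometry,
    cap: int = FULL_PRODUCT_CAP,
) -> AggregateHamiltonian:
    """Exact product-space dimer Hamiltonian, every coupling element kept.

    Naive double loop over all configuration pairs; no neglect rules, no
    windowing.  Errors out above ``cap`` configurations.
    """
    n1, n2 = m1.n_states, m2.n_states
    if n1 * n2 > cap:
        raise ValueError(f"{n1 * n2} configurations exceed the oracle cap {cap}")

    R1 = np.asarray(m1.orientation, dtype=float)
    d1 = np.einsum("ab,ijb->ija", R1, m1.dipoles)
    Rg = _axis_angle_matrix(geometry.separation, geometry.rotation_deg)
    d2 = np.einsum(
        "ab,ijb->ija", Rg @ np.asarray(m2.orientation, dtype=float), m2.dipoles
    )
    X = np.asarray(geometry.separation, dtype=float)

    pairs = [(a, b) for a in range(n1) for b in range(n2)]
    configs = [
        ExcitonConfiguration(a, b, float(m1.energies[a] + m2.energies[b]))
        for (a, b) in pairs
    ]
    order = sorted(
        range(len(configs)),
        key=lambda k: (configs[k].zeroth_order_energy, configs[k].state_1, configs[k].state_2),
    )
    configs = [configs[k] for k in order]
    pairs = [pairs[k] for k in order]

    N = len(pairs)
    H = np.zeros((N, N), dtype=complex)
    for p in range(N):
        A, B = pairs[p]
        for q in range(N):
            D, C = pairs[q]
            J = _naive_coupling(d1[A, D], d2[B, C], X) * HARTREE_EV
            H[p, q] += J
            if p == q:
                H[p, p] += m1.energies[A] + m2.energies[B]

    basis = ExcitonBasis(configs, "TPA", None)
    return AggregateHamiltonian(H, basis, d1, d2, RuleFlags.all_off())


def direct_rixs_amplitude(
    eig: EigenSystem,
    i: int,
    f: int,
    e_exc: float,
    gammas,
    e1=(1.0, 0.0, 0.0),
    e2=(0.0, 1.0, 0.0),
    intermediate_indices=None,
) -> complex:
    """Kramers-Heisenberg inner sum by explicit loop at fixed polarizations.

    ``gammas`` is a per-eigenstate array of lifetime widths Γ_n (eV).
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    n_states = eig.energies.size
    if not (0 <= i < n_states and 0 <= f < n_states):
        raise IndexError("initial/final index out of range")
    n_iter = (
        range(n_states)
        if intermediate_indices is None
        else [int(k) for k in intermediate_indices]
    )
    amp = 0.0 + 0.0j
    for n in n_iter:
        num = (e2 @ eig.dipoles[f, n]) * (e1 @ eig.dipoles[n, i])
        den = eig.energies[i] + e_exc - eig.energies[n] - 1j * gammas[n]
        amp += num / den
    return complex(amp)
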