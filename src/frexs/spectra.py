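"""First- and second-order X-ray spectra from a dimer (or monomer) eigensystem.

XAS is a weighted stick spectrum,

    S_XAS(E) = sum_i w(E_i) (E_f - E_i) |e1 . d_fi|^2  delta(E - E_f + E_i),

broadened by a Voigt profile that combines the final-state lifetime Lorentzian
Γ(E_f) with the Gaussian excitation-pulse width σ.  RIXS is the
Kramers-Heisenberg double sum with a coherent inner sum over intermediate
states,

    S_RIXS(E_exc, E_em) = sum_i w_i sum_f
        | sum_n (e2 . d_fn)(e1 . d_ni) / (E_i + E_exc - E_n - i Γ_n) |^2

with the emission-energy delta replaced by the pulse Gaussian; Γ_n is an
energy-dependent core-hole lifetime looked up from a piecewise-constant band
model.  PFY integrates the RIXS map over a fixed emission range.

Polarization handling: ``isotropic`` uses the factorized orientational
average <|e2 . A . e1|^2> = (1/9) Σ_ab |A_ab|^2 (independent isotropic e1,
e2); ``perpendicular-detection`` averages numerically over molecular
orientations with crossed lab polarizations e1 = x, e2 = y, emulating freely
tumbling molecules with polarization-resolved detection.  A fixed-polarization
mode exists for validation against explicit amplitude loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import voigt_profile

from .hamiltonian import EigenSystem
from .monomer import K_B_EV

ISOTROPIC = "isotropic"
PERPENDICULAR = "perpendicular-detection"

BOLTZMANN_ALL_GROUND = "boltzmann-all-ground"
LOWEST_KRAMERS_DOUBLET = "lowest-kramers-doublet"

HEMIN_GLOBAL_SHIFT = -2.8
"""Absolute energy shift (eV) conventionally applied to rendered spectra."""

PFY_RANGE = (695.0, 735.0)
"""Emission-energy integration range (eV) of the 3d -> 2p decay channel."""


class SpectrumWarning(UserWarning):
    pass


@dataclass(frozen=True)
class FixedPolarization:
    """Fixed lab-frame polarizations, for single-orientation calculations."""

    e1: tuple = (1.0, 0.0, 0.0)
    e2: tuple = (0.0, 1.0, 0.0)


@dataclass
class GammaModel:
    """Piecewise-constant lifetime broadening Γ(E).

    ``bounds`` are strictly increasing band edges (eV); ``gammas`` has one
    more entry than ``bounds``.  An energy exactly at an edge belongs to the
    upper band.
    """

    bounds: np.ndarray
    gammas: np.ndarray

    def __init__(self, bounds, gammas):
        self.bounds = np.asarray(bounds, dtype=float)
        self.gammas = np.asarray(gammas, dtype=float)
        if self.gammas.shape[0] != self.bounds.shape[0] + 1:
            raise ValueError("need exactly one more Γ than band edges")
        if self.bounds.size and np.any(np.diff(self.bounds) <= 0):
            raise ValueError("band edges must be strictly increasing")
        if np.any(self.gammas <= 0):
            raise ValueError("all Γ must be positive")

    @classmethod
    def constant(cls, gamma: float) -> "GammaModel":
        return cls([], [gamma])

    def __call__(self, energies):
        return gamma_of_energy(energies, self)


HEMIN_GAMMA_MODEL = GammaModel(
    bounds=[709.2, 711.6, 719.2], gammas=[0.09, 0.26, 0.43, 0.61]
)
"""L-edge lifetime bands: 0.09 eV below 709.2 eV, 0.26 to 711.6 eV,
0.43 to 719.2 eV, 0.61 eV above."""


def gamma_of_energy(energies, model: GammaModel):
    """Lifetime Γ(E) lookup; an energy on a band edge takes the upper band."""
    e = np.asarray(energies, dtype=float)
    idx = np.searchsorted(model.bounds, e, side="right")
    out = model.gammas[idx]
    return float(out) if np.isscalar(energies) else out


def boltzmann_weights(initial_energies, temperature: float):
    """Normalized Boltzmann weights; at T = 0 the degenerate minimum set
    shares all weight equally."""
    e = np.asarray(initial_energies, dtype=float)
    if e.size == 0:
        raise ValueError("no initial states given")
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if temperature == 0:
        w = np.isclose(e, e.min(), atol=1e-12).astype(float)
    else:
        w = np.exp(-(e - e.min()) / (K_B_EV * temperature))
    return w / w.sum()


@dataclass
class SpectroscopyConfig:
    """Everything the spectrum calculators need besides the eigensystem.

    ``pulse_sigma`` is the Gaussian width σ of the excitation pulse (eV);
    ``global_shift`` is added to rendered energy axes only — eigenvalues and
    the Γ(E) lookup stay on the theory scale.  ``initial_state_mode`` selects
    either all near-ground eigenstates Boltzmann-weighted at ``temperature``
    (states within ``ground_span`` of the minimum) or only the degenerate
    lowest Kramers set with equal weights.
    """

    excitation_grid: np.ndarray = None
    emission_grid: np.ndarray = None
    pulse_sigma: float = 0.25
    temperature: float = 300.0
    polarization_geometry: object = ISOTROPIC
    global_shift: float = 0.0
    gamma_model: GammaModel = field(default_factory=lambda: HEMIN_GAMMA_MODEL)
    initial_state_mode: str = BOLTZMANN_ALL_GROUND
    ground_span: float = 0.01
    degeneracy_tol: float = 1e-6
    quadrature_order: int = 8

    def __post_init__(self):
        for name in ("excitation_grid", "emission_grid"):
            g = getattr(self, name)
            if g is not None:
                g = np.asarray(g, dtype=float)
                if g.ndim != 1 or (g.size > 1 and np.any(np.diff(g) <= 0)):
                    raise ValueError(f"{name} must be strictly increasing 1D")
                setattr(self, name, g)
        if not self.pulse_sigma > 0:
            raise ValueError("pulse_sigma must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class SpectrumGrid:
    """1D spectrum: energy axis (eV) and non-negative intensities (arb. u.)."""

    energies: np.ndarray
    intensities: np.ndarray

    def to_text(self, path, header="# energy_eV intensity"):
        np.savetxt(path, np.column_stack([self.energies, self.intensities]),
                   header=header.lstrip("# "))


@dataclass
class RixsMap:
    """2D RIXS: intensity[i_exc, i_em] over excitation x emission grids (eV)."""

    excitation_energies: np.ndarray
    emission_energies: np.ndarray
    intensities: np.ndarray
    warning: str | None = None

    def to_text(self, path):
        with open(path, "w") as fh:
            fh.write("# excitation_eV emission_eV intensity\n")
            for i, ex in enumerate(self.excitation_energies):
                for j, em in enumerate(self.emission_energies):
                    fh.write(f"{ex:.6f} {em:.6f} {self.intensities[i, j]:.8e}\n")


def select_initial_states(eig: EigenSystem, config: SpectroscopyConfig):
    """Initial eigenstates and their statistical weights.

    ``boltzmann-all-ground``: every eigenstate within ``ground_span`` of the
    minimum, Boltzmann-weighted at ``temperature``.
    ``lowest-kramers-doublet``: only states degenerate with the minimum
    (within ``degeneracy_tol``), equally weighted — the low-temperature
    convention for dimer products of the lowest Kramers doublets.
    """
    e = eig.energies
    if config.initial_state_mode == BOLTZMANN_ALL_GROUND:
        idx = np.nonzero(e - e.min() <= config.ground_span)[0]
        w = boltzmann_weights(e[idx], config.temperature)
    elif config.initial_state_mode == LOWEST_KRAMERS_DOUBLET:
        idx = np.nonzero(e - e.min() <= config.degeneracy_tol)[0]
        w = np.full(idx.size, 1.0 / idx.size)
    else:
        raise ValueError(f"unknown initial_state_mode {config.initial_state_mode!r}")
    if idx.size == 0:
        raise ValueError("no initial states selected")
    return idx, w


# ---------------------------------------------------------------------------
# orientational averaging

def so3_quadrature(order: int):
    """Euler-angle product quadrature over SO(3) with the invariant measure.

    ``order`` uniform points in each of α, γ ∈ [0, 2π) and ``order``
    Gauss-Legendre nodes in cos β.  Exact for band-limited functions up to
    the trigonometric degree of the node counts; intensities are degree-4
    polynomials in the rotation-matrix entries, so modest orders converge.
    Returns a list of (rotation matrix, weight); weights sum to 1.
    """
    if order < 1:
        raise ValueError("quadrature order must be >= 1")
    alphas = 2 * np.pi * np.arange(order) / order
    gammas = 2 * np.pi * np.arange(order) / order
    u, wu = np.polynomial.legendre.leggauss(order)  # u = cos beta on [-1, 1]
    betas = np.arccos(u)
    nodes = []
    for b, wb in zip(betas, wu / 2.0):
        cb, sb = np.cos(b), np.sin(b)
        Rb = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        for a in alphas:
            ca, sa = np.cos(a), np.sin(a)
            Ra = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
            for g in gammas:
                cg, sg = np.cos(g), np.sin(g)
                Rg = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
                nodes.append((Ra @ Rb @ Rg, wb / (order * order)))
    return nodes


def orientational_average(
    evaluator,
    order: int = 8,
    tol: float = 1e-6,
    max_order: int = 64,
    converge: bool = True,
):
    """Rotational average of ``evaluator(R)`` over SO(3).

    With ``converge=True`` the quadrature order is doubled until the result
    changes by less than ``tol`` (relative); exceeding ``max_order`` raises.
    """
    def _avg(n):
        total = None
        for R, w in so3_quadrature(n):
            v = np.asarray(evaluator(R), dtype=float) * w
            total = v if total is None else total + v
        return total

    val = _avg(order)
    if not converge:
        return val
    while True:
        if 2 * order > max_order:
            raise RuntimeError(
                f"orientational average not converged to {tol} at order {order} "
                f"(cap {max_order})"
            )
        nxt = _avg(2 * order)
        scale = max(np.max(np.abs(val)), np.max(np.abs(nxt)), 1e-300)
        if np.max(np.abs(nxt - val)) / scale < tol:
            return nxt
        val, order = nxt, 2 * order


# ---------------------------------------------------------------------------
# XAS

def xas(eig: EigenSystem, config: SpectroscopyConfig) -> SpectrumGrid:
    """Absorption spectrum on ``config.excitation_grid``.

    Stick weights w_i (E_f - E_i) |d_fi|^2 / 3 (isotropic orientational
    average of |e1 . d|^2), Voigt-broadened with Lorentzian Γ(E_f) and
    Gaussian σ, then shifted by ``global_shift``.
    """
    if config.excitation_grid is None:
        raise ValueError("config.excitation_grid is required for XAS")
    idx, w = select_initial_states(eig, config)
    grid = config.excitation_grid
    out = np.zeros_like(grid)
    for i, wi in zip(idx, w):
        de = eig.energies - eig.energies[i]
        d2 = np.sum(np.abs(eig.dipoles[:, i, :]) ** 2, axis=1)
        for f in np.nonzero(de > config.degeneracy_tol)[0]:
            weight = wi * de[f] * d2[f] / 3.0
            if weight == 0:
                continue
            gam = gamma_of_energy(eig.energies[f], config.gamma_model)
            out += weight * voigt_profile(
                grid - (de[f] + config.global_shift), config.pulse_sigma, gam
            )
    return SpectrumGrid(grid.copy(), out)


# ---------------------------------------------------------------------------
# RIXS

def rixs_amplitude_tensor(
    eig: EigenSystem,
    i: int,
    e_exc: float,
    config: SpectroscopyConfig,
    intermediate_indices=None,
):
    """Polarizability-like tensor A[f, a, b] = Σ_n d_fn,a d_ni,b / denom_n.

    The coherent inner sum of the Kramers-Heisenberg amplitude; contracting
    with polarizations gives e2 . A[f] . e1.  ``intermediate_indices`` limits
    the sum (energy-window pre-selection); default is all eigenstates.
    """
    n_idx = (
        np.arange(eig.energies.size)
        if intermediate_indices is None
        else np.asarray(intermediate_indices, dtype=int)
    )
    gam = gamma_of_energy(eig.energies[n_idx], config.gamma_model)
    denom = eig.energies[i] + e_exc - eig.energies[n_idx] - 1j * np.atleast_1d(gam)
    d_ni = eig.dipoles[n_idx, i, :]  # (nw, 3)
    d_fn = eig.dipoles[:, n_idx, :]  # (N, nw, 3)
    return np.einsum("fna,nb->fab", d_fn, d_ni / denom[:, None])


def _intensities_from_tensor(A, geometry, quadrature_order):
    """Orientation/polarization reduction of |e2 . A[f] . e1|^2 per final state."""
    if geometry == ISOTROPIC:
        return np.sum(np.abs(A) ** 2, axis=(1, 2)) / 9.0
    if isinstance(geometry, FixedPolarization):
        e1 = np.asarray(geometry.e1, dtype=float)
        e2 = np.asarray(geometry.e2, dtype=float)
        return np.abs(np.einsum("a,fab,b->f", e2, A, e1)) ** 2
    if geometry == PERPENDICULAR:
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])

        def evaluator(R):
            Arot = np.einsum("ca,fab,db->fcd", R, A, R)
            return np.abs(np.einsum("a,fab,b->f", e2, Arot, e1)) ** 2

        return orientational_average(
            evaluator, order=quadrature_order, converge=False
        )
    raise ValueError(f"unknown polarization geometry {geometry!r}")


def rixs(
    eig: EigenSystem,
    config: SpectroscopyConfig,
    excitation_energies,
    intermediate_window=None,
) -> RixsMap:
    """Kramers-Heisenberg RIXS map on excitation x emission grids.

    ``excitation_energies`` are incident energies on the theory scale (the
    ``global_shift`` is applied to the rendered axes).  With
    ``intermediate_window = (center, half_width)`` the coherent sum runs only
    over intermediate eigenstates inside the window; an empty window yields a
    zero map with a warning.  Emission lines at
    E_em = E_exc + E_i - E_f carry the pulse Gaussian of width σ.
    """
    if config.emission_grid is None:
        raise ValueError("config.emission_grid is required for RIXS")
    exc = np.asarray(excitation_energies, dtype=float)
    idx, w = select_initial_states(eig, config)

    warning = None
    if intermediate_window is None:
        n_idx = np.arange(eig.energies.size)
    else:
        center, half_width = intermediate_window
        n_idx = np.nonzero(np.abs(eig.energies - center) <= half_width)[0]
        if n_idx.size == 0:
            warning = "intermediate-state window is empty; RIXS map is zero"
            warnings.warn(warning, SpectrumWarning, stacklevel=2)

    em = config.emission_grid
    out = np.zeros((exc.size, em.size))
    sig = config.pulse_sigma
    norm = 1.0 / (sig * np.sqrt(2 * np.pi))
    if n_idx.size:
        for k, e_exc in enumerate(exc):
            for i, wi in zip(idx, w):
                A = rixs_amplitude_tensor(eig, i, e_exc, config, n_idx)
                inten = wi * _intensities_from_tensor(
                    A, config.polarization_geometry, config.quadrature_order
                )
                centers = e_exc + eig.energies[i] - eig.energies + config.global_shift
                for f in np.nonzero(inten > 0)[0]:
                    out[k] += inten[f] * norm * np.exp(
                        -((em - centers[f]) ** 2) / (2 * sig**2)
                    )
    return RixsMap(exc + config.global_shift, em.copy(), out, warning)


def pfy(rixs_map: RixsMap, e_min: float = PFY_RANGE[0], e_max: float = PFY_RANGE[1]) -> SpectrumGrid:
    """Partial fluorescence yield: the RIXS map integrated (trapezoid rule)
    over emission energies in [e_min, e_max], per excitation energy."""
    if not e_min < e_max:
        raise ValueError("require e_min < e_max")
    em = rixs_map.emission_energies
    mask = (em >= e_min) & (em <= e_max)
    if mask.sum() < 2:
        raise ValueError(
            f"emission grid has no overlap with [{e_min}, {e_max}] eV"
        )
    vals = np.trapezoid(rixs_map.intensities[:, mask], x=em[mask], axis=1)
    return SpectrumGrid(rixs_map.excitation_energies.copy(), vals)
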