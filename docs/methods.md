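# Methods

## Model

An aggregate of monomers held together by van der Waals forces is described
in a Frenkel-exciton picture: with negligible wave-function overlap between
monomers, aggregate states are Hartree products |A₁ B₂⟩ of monomer
eigenstates and the aggregate Hamiltonian is

- diagonal: zeroth-order energies E_A¹ + E_B²,
- off-diagonal: Coulomb couplings between the monomer transitions A₁→D₁ and
  B₂→C₂, evaluated in the point-dipole approximation
  J = d_AD·d_BC/|X|³ − 3(X·d_AD)(X·d_BC)/|X|⁵ with the center-to-center
  vector X in atomic units, converted once to eV
  (1 hartree = 27.211386245988 eV).

This is valid when |X| is large compared to the extent of the transition
densities; for metal-centered 2p→3d transitions the densities are compact,
so the approximation holds even at close stacking distances. Exchange terms,
beyond-dipole transition-density integrals and monopole (charge) couplings
are outside the model's scope.

Spin-orbit coupling makes the monomer transition dipoles complex. The
contraction inside J is **bilinear** (no conjugation): Hermiticity of the
aggregate Hamiltonian then follows from the Hermiticity of the monomer
dipole matrices d[A][B] = conj(d[B][A]), which the monomer validator
enforces (componentwise tolerance 1e-10 a.u. by default, configurable to
absorb file round-trip noise). This convention is exercised by tests with
randomly phased complex dipoles.

## Bases and truncations

- **OPA** (one-particle): ground products plus single excitations |a₁ g₂⟩,
  |g₁ a₂⟩. Adequate for the one-photon XAS only.
- **TPA** (two-particle): the full product space — exact for a dimer —
  needed for RIXS, where the two-photon pathway g → c → a interferes across
  configurations of type |a₁ c₂⟩.
- Coupling-neglect rules: (a) couplings of g↔v transitions with g↔v and with
  v↔c transitions are zeroed (these channels are weak at the L edge compared
  with the dipole-allowed 2p→3d ones); (b) static dipoles do not couple to
  anything, which also keeps the trace of the Hamiltonian equal to the sum
  of zeroth-order energies. Cross couplings such as g↔c with v↔c are *kept*
  by default; every rule is individually switchable (`RuleFlags`), and
  switching everything off reproduces the exact product-space Hamiltonian
  (verified against an independent brute-force assembly to 1e-12 eV).
- Rule (c), core-state windowing: only core states within
  ±(multiplier × σ) of the pulse center enter the basis (closed interval on
  both ends; applied per core state, not per configuration). With the
  defaults σ = 0.25 eV and multiplier 5 this is ±1.25 eV. Windowing is
  monotone: enlarging the window never removes configurations.

Two counting conventions exist for the basis rank. `build_basis` uses set
semantics (the full product space for TPA). `count_basis` implements the
bookkeeping ledger 2·n_val·n_core + 2·n_val (TPA), a multiset count in which
the all-ground product appears in both single-excitation terms; it is the
convention that reproduces the published rank 140,964 for 102
valence-manifold + 690 core states. Both are documented and tested; physics
tests use the unambiguous set semantics.

Energies are stored relative to each monomer's ground state, and the
aggregate Hamiltonian is assembled shift-free; the conventional absolute
shift (−2.8 eV for the hemin comparison) is applied only to rendered
spectrum axes. The Γ(E) lifetime lookup likewise uses unshifted eigenvalues.

## Spectra

- **XAS**: stick weights w(E_i)·(E_f − E_i)·|d_fi|²/3 (isotropic average of
  |e₁·d|²), convolved with a Voigt profile combining the Lorentzian
  final-state lifetime Γ(E_f) with the Gaussian pulse width σ. The
  (E_f − E_i) prefactor is retained as the oscillator-strength-like
  weighting of the underlying expression.
- **RIXS**: the Kramers-Heisenberg amplitude tensor
  A[f,α,β] = Σ_n d_fn,α d_ni,β / (E_i + E_exc − E_n − iΓ_n) is formed per
  initial state and excitation energy (optionally restricted to intermediate
  eigenstates inside the energy window); the squared, orientation-reduced
  amplitude is placed on the emission grid as a Gaussian of width σ at
  E_em = E_exc + E_i − E_f. Γ_n enters inside the amplitude (Lorentzian in
  the denominator), the pulse Gaussian replaces the emission delta; the two
  broadening mechanisms are not double-counted.
- **PFY**: trapezoidal integration of the RIXS map over a fixed emission
  range (default 695–735 eV, the 3d→2p radiative channel).
- **Lifetime bands**: piecewise-constant Γ(E) with the L-edge defaults
  0.09 eV below 709.2 eV, 0.26 to 711.6 eV, 0.43 to 719.2 eV, 0.61 above;
  an energy exactly on a band edge takes the upper band, matching the
  below/between/above wording the bands come from.
- **Initial states**: either all eigenstates within `ground_span`
  (default 0.01 eV) of the minimum, Boltzmann-weighted
  (k_B = 8.617333262×10⁻⁵ eV/K, default 300 K), or only the states
  degenerate with the minimum, equally weighted — the low-temperature
  convention for a dimer starting from products of both monomers' lowest
  Kramers doublets (four states).

### Polarization and orientational averaging

`isotropic` uses the factorized average
⟨|e₂·A·e₁|²⟩ = (1/9)Σ_ab|A_ab|² (independent isotropic polarizations); it
is exactly rotation-invariant. `perpendicular-detection` emulates freely
tumbling molecules with the outgoing polarization detected orthogonal to
the incoming one: crossed lab polarizations e₁ = x̂, e₂ = ŷ and a numerical
average over molecular orientations. The SO(3) quadrature is a product rule
(uniform in the Euler angles α, γ; Gauss-Legendre in cos β) with weights
summing to one; intensities are degree-4 polynomials in the rotation-matrix
entries, so order 8–10 is effectively exact (rigid rotation of the whole
dimer changes averaged spectra by < 1e-8 relative in the tests). A
convergence helper doubles the order until the result changes by < 1e-6
relative and raises past a cap. A closed-form tensor-invariant average for
the crossed geometry was deliberately not committed to; the numerical
average is the contract, with the isotropic closed form available as a
cross-check. A fixed-polarization mode exists for validating against
explicit amplitude loops.

## Synthetic monomers

The generator emulates the *structure* of a hemin-like L-edge absorber, not
its values: a ground manifold of Kramers doublets split by
`ground_splitting` (default 5 meV — the unpublished spin-orbit splitting of
a ground sextet is of this order, comparable to k_BT/5 at 300 K), a valence
manifold drawn uniformly in (0.5, 7.3] eV, a core manifold uniform in
710.6–732.9 eV, and Hermitian random complex dipoles with block scales
g↔c = 0.05, v↔c = 0.02, g↔v = 0.005 a.u. (free parameters; the hierarchy
mirrors the dominance of the dipole-allowed 2p→3d channel, and the absolute
scale keeps couplings at 7 a.u. in the meV range typical of weak excitonic
interaction). Phases are uniform on the unit circle so that complex
conjugation errors cannot hide. The `hemin-like-full-counts` preset
reproduces the published bookkeeping exactly: 6 ground + 96 valence + 690
core = 792 spin-orbit states, of which 102 belong to the valence manifold
(ground included).

What the generator does **not** emulate: multiplet structure within
manifolds, realistic dipole magnitudes or selection rules beyond the block
hierarchy, vibronic effects, or conformational flexibility. Passing tests
therefore demonstrate the correctness of the exciton machinery — basis
construction, coupling rules, diagonalization, spectral formulas — not
quantitative agreement with any measured hemin spectrum, which would require
actual multiconfigurational monomer data as input.

## Numerical choices

- Dense Hermitian diagonalization (`eigh`) with a configurable size cap
  (default 4000); exceeding it raises with a pointer to windowing rather
  than silently truncating. Desk-scale problems in the tests and examples
  use monomers of ≤ 34 states (basis ranks ≤ ~1200); the full-count preset
  exists for bookkeeping, not for diagonalization.
- Degenerate eigenvalues (Kramers degeneracy is pervasive): no gauge is
  fixed; all observables compared in tests are gauge-invariant sums over
  degenerate subspaces.
- The exchange format is versioned JSON; floats round-trip bit-exactly.
  Loading sorts states ascending by energy with a stable index map.
- Window and Γ-band boundary cases are closed/upper-band by convention, as
  stated above; manifold classification uses E ≤ ground_span (ground),
  E < core_threshold (valence), E ≥ core_threshold (core).

## Known limitations

- Dimers only (the basis builder is n-monomer-ready in design, but only the
  two-monomer path is implemented and tested).
- Point-dipole Coulomb couplings only; no exchange, no transition-density
  integrals, no charged-system monopole terms.
- Two additivity caveats of the second-order formula, documented because the
  zero-coupling limit is a natural correctness check: even for an
  *uncoupled* pair, (i) the strictly elastic RIXS channel is coherent across
  monomers (the inner sum spans both monomers' intermediates before
  squaring), and (ii) two-particle Raman final states (both monomers
  valence-excited) exist in the dimer but have no monomer counterpart. XAS
  is strictly additive; RIXS is additive channel-by-channel for all
  single-excitation finals, and exactly additive as a map when the monomers'
  channels are polarization-decoupled and the g↔v dipoles vanish — the
  configuration the additivity tests use.
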