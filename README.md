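# frexs

Frenkel-exciton simulation of metal **L-edge X-ray spectra of molecular
dimers**: X-ray absorption (XAS), resonant inelastic X-ray scattering (RIXS)
and partial fluorescence yield (PFY).

## The problem

L-edge spectroscopy of transition-metal complexes probes 2p → 3d excitations
whose description needs multiconfigurational wave functions with spin-orbit
coupling — hundreds of electronic states per metal center. For aggregates
(e.g. hemin, which dimerizes in aqueous solution), a supermolecular treatment
of the full dimer is computationally out of reach: the number of required
spin-orbit states grows from 792 for one monomer to over 137,000 for the pair.

`frexs` takes the exciton route instead. The monomers are solved separately
(by whatever quantum-chemistry program you like — that part is *input*, not
done here); the dimer states are built as Hartree products |A₁ B₂⟩ of monomer
eigenstates, coupled by the point-dipole approximation to the inter-monomer
Coulomb interaction,

```
J = d_AD · d_BC / |X|³ − 3 (X·d_AD)(X·d_BC) / |X|⁵
```

with `X` the center-to-center vector and `d_AD = ⟨A|d|D⟩` the (complex,
spin-orbit) monomer transition dipoles. Diagonalizing the resulting aggregate
Hamiltonian gives eigenstates |i⟩, |n⟩, |f⟩ and dipoles `d_ni`, `d_fn`, from
which

- **XAS**: `S(E) = Σ_i w(E_i) (E_f − E_i) |e₁·d_fi|² δ(E − E_f + E_i)`,
- **RIXS** (Kramers-Heisenberg):
  `S(E_exc, E_em) = Σ_i w_i Σ_f |Σ_n (e₂·d_fn)(e₁·d_ni) / (E_i + E_exc − E_n − iΓ_n)|²`,
- **PFY**: the RIXS map integrated over an emission window,

are computed with energy-dependent core-hole lifetimes Γ(E), Gaussian pulse
broadening, Boltzmann initial-state weights and orientational averaging.

Physically motivated truncations keep it tractable: one-particle (OPA) or
two-particle (TPA) exciton bases, neglect of the weak g↔v coupling classes and
of static-dipole couplings, and a ±5σ energy window pre-selecting core states
around the excitation pulse (±1.25 eV for a 0.25 eV pulse), which cuts the
full TPA rank of 140,964 (for 102 valence-manifold + 690 core states) to a
desk-scale block.

No external data are required: a seeded synthetic-monomer generator produces
hemin-like fixtures with the right manifold structure.

## Worked example

```sh
python examples/01_davydov_dimer.py
```

```
coupling J                : 0.5077 meV
eigenvalues of the c/g pair: 709.999492, 710.000508 eV
Davydov splitting          : 1.0155 meV (closed form 1.0155)
```

Two identical two-level monomers (core transition at 710 eV, dipole 0.08 a.u.
perpendicular to the 7 a.u. stacking axis) produce the textbook Davydov pair:
the degenerate single-excitation configurations split by exactly 2J, with
J = |d|²/R³ converted from atomic units to eV. The other examples build a
monomer XAS with the lifetime-band model, a windowed dimer RIXS/PFY
calculation, and the state-count bookkeeping above.

A thin CLI mirrors the library for file-based workflows:

```sh
frexs toy-monomer --preset hemin-like-small -o mono.json
frexs xas mono.json --config cfg.yaml -o xas.tsv
```

## Layout

- `src/frexs/monomer.py` — monomer exchange format (JSON), manifold
  classification, SOC state bookkeeping
- `src/frexs/basis.py` — OPA/TPA exciton bases, core-state windowing
- `src/frexs/hamiltonian.py` — dipole-dipole couplings, neglect rules,
  assembly, diagonalization
- `src/frexs/spectra.py` — XAS / RIXS / PFY, lifetime bands, broadening,
  orientational averaging
- `src/frexs/synthetic.py` — seeded hemin-like fixture generator
- `src/frexs/oracle.py` — brute-force reference paths (tests only)
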