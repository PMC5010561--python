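"""L-edge absorption spectrum of a synthetic hemin-like monomer.

Builds a seeded toy monomer (2 ground Kramers states, 12 valence, 20 core
states in the 710.6-732.9 eV range), computes the Boltzmann-weighted XAS
with the energy-dependent lifetime bands and the 0.25 eV pulse width, and
prints the strongest absorption features.
"""

import numpy as np

from frexs import (
    SpectroscopyConfig,
    make_preset,
    monomer_eigensystem,
    xas,
)

monomer = make_preset("hemin-like-small")
eig = monomer_eigensystem(monomer)

config = SpectroscopyConfig(
    excitation_grid=np.linspace(700, 740, 2000),
    temperature=300.0,
    global_shift=-2.8,  # conventional absolute shift of the rendered axis
)
spectrum = xas(eig, config)

print(f"grid: {spectrum.energies[0]:.0f}-{spectrum.energies[-1]:.0f} eV, "
      f"{spectrum.energies.size} points")
peak = np.argmax(spectrum.intensities)
print(f"strongest absorption at {spectrum.energies[peak]:.2f} eV "
      f"(intensity {spectrum.intensities[peak]:.3e} arb. u.)")
total = np.trapezoid(spectrum.intensities, spectrum.energies)
print(f"integrated intensity {total:.3e} arb. u. eV")
# Peak positions reflect the seeded core-state energies minus the 2.8 eV
# shift; intensities combine the (E_f - E_i) prefactor with |d|^2/3.
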