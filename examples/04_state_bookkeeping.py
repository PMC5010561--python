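"""State-count bookkeeping: why the exciton decomposition pays off.

A monomer with 16 sextet and 174 quartet spin-free states carries 792
spin-orbit coupled states.  Treating the dimer as one supermolecule at the
same level would need 137,426 SOC states; the two-particle exciton basis
instead has rank 140,964, which the +/-5-sigma core-state window cuts to a
tractable block.
"""

from frexs import count_basis, count_soc_states, select_core_window

monomer_soc = count_soc_states({6: 16, 4: 174})
super_soc = count_soc_states({6: 61, 4: 34265})
print(f"monomer SOC states            : {monomer_soc}")
print(f"supermolecule dimer SOC states: {super_soc}")

tpa = count_basis(n_val=102, n_core=690, approximation="TPA")
opa = count_basis(n_val=102, n_core=690, approximation="OPA")
print(f"TPA exciton basis rank        : {tpa}")
print(f"OPA exciton basis rank        : {opa}")

_, half_width = select_core_window([710.0], center=710.0, sigma=0.25, multiplier=5)
# ~60 of 690 core states fall inside a typical +/-1.25 eV window, so the
# windowed TPA rank drops to roughly 2 * 102 * 60 ~ 12,000-22,000 depending
# on the excitation energy.
windowed = count_basis(102, 60, "TPA")
print(f"window half-width             : {half_width} eV")
print(f"windowed TPA rank (60 cores)  : {windowed}")
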