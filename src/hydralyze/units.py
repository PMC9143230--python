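"""Unit conventions and conversion constants.

Internal units follow the GRO convention throughout: length nm, time ps,
mass amu, charge e.  Everything that leaves these units does so through a
constant defined here, once.
"""

#: amu / nm^3  ->  g / cm^3.
#: 1 amu = 1.66053906660e-24 g and 1 nm^3 = 1e-21 cm^3.
AMU_PER_NM3_TO_G_PER_CM3 = 1.66053906660e-3

#: nm^2 / ps  ->  units of 1e-5 cm^2/s (the customary scale for water
#: self-diffusion).  1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s
#: = 1e3 x (1e-5 cm^2/s); conversely 1e-5 cm^2/s = 1e-3 nm^2/ps.
NM2_PER_PS_TO_1E5_CM2_PER_S = 1.0e3
D_1E5_CM2_PER_S_TO_NM2_PER_PS = 1.0e-3

#: Angstrom -> nm, for PDB input.
ANGSTROM_TO_NM = 0.1

#: SPC rigid water geometry and charges.
SPC_OH_BOND_NM = 0.1
SPC_HOH_ANGLE_DEG = 109.47
SPC_CHARGE_O = -0.82
SPC_CHARGE_H = 0.41
SPC_MASS_O = 15.9994
SPC_MASS_H = 1.008
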