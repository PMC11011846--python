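"""Physical constants and package-wide unit conventions.

Units used throughout: molecular weight in kDa, volume in mL, concentration
in mg/mL, intrinsic viscosity [eta] in mL/g, specific absorbance increment
dA/dc in mL g^-1 cm^-1, refractive-index increment dn/dc in mL/g,
hydrodynamic radius in nm, temperature in K.
"""

AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN = 1.380649e-23  # J/K

#: dn/dc of unmodified protein in aqueous buffer, mL/g. Used for every
#: species and complex (all-protein assumption; glycan contribution ignored).
PROTEIN_DN_DC = 0.185
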