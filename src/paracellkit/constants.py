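"""Physical constants used throughout the package.

All electrophysiology is done in CGS-flavoured units that are conventional
for epithelial transport work: permeabilities in cm/s, concentrations in
mol/cm^3 (1 mM = 1e-6 mol/cm^3), resistances in Ohm*cm^2.
"""

#: Gas constant, J mol^-1 K^-1
R_GAS = 8.314

#: Faraday constant, C mol^-1
FARADAY = 96485.0

#: Default assay temperature (37 degC), K
T_BODY_K = 310.15

#: Average mass of one water molecule, Da (added once per peptide chain)
WATER_MASS_DA = 18.02

#: mM -> mol/cm^3
MM_TO_MOL_PER_CM3 = 1e-6
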