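"""Physical constants used across the package.

Lengths are in Å, electron densities in e⁻/Å³, surface excesses in mg/m²,
bulk concentrations in mol/L unless a function says otherwise.
"""

#: Classical electron radius (Å).
R_E = 2.8179403e-5

#: Avogadro constant (1/mol).
N_A = 6.02214e23

#: Molar gas constant (J mol⁻¹ K⁻¹).
R_GAS = 8.314462618

#: Electrons per water molecule.
WATER_ELECTRONS = 10.0

#: Molar mass of water (g/mol).
WATER_MOLAR_MASS = 18.015

#: Electron density of pure water near room temperature (e⁻/Å³),
#: from its mass density and 10 electrons per molecule.
RHO_WATER = 0.334

#: Default laboratory temperature, 23 °C (K).
DEFAULT_TEMPERATURE = 296.15

#: Clean air-water interfacial tension at 23 °C (mN/m).
GAMMA0_WATER = 72.5

#: Å² → m² conversion.
A2_TO_M2 = 1e-20
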