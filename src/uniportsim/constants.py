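"""Physical constants and unit-conversion factors used across the package."""

#: Avogadro constant, mol^-1 (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Molar volume of water, L mol^-1 (18 mL/mol).
WATER_MOLAR_VOLUME = 0.018

#: mol L^-1 -> mol m^-3 (equivalently m^3 -> L).
M3_TO_L = 1000.0
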