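"""Physical constants (CODATA 2018) used for rate/barrier interconversion.

Energies are in kcal/mol throughout the package; temperatures in kelvin.
"""

BOLTZMANN_J_PER_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34

#: Gas constant in kcal/(mol K).
R_KCAL = 1.98720425864083e-3
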