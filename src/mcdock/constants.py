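"""Physical constants and unit conventions.

All energies are kcal/mol, distances Å, temperatures K, masses amu,
times ps. These are the conventional units of biomolecular force
fields and are used consistently across the package.
"""

#: Boltzmann constant in kcal/(mol·K).
KB = 0.0019872041

#: 1 kcal/mol expressed in amu·Å²/ps² (for the Langevin integrator).
KCAL_PER_MOL_IN_AMU_A2_PS2 = 418.4
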