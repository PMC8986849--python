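"""Physical constants used throughout (CODATA 2018, immutable by convention).

Free energies are reported in kcal/mol, entropies in cal/(K mol) — the
customary units in host–guest thermochemistry tables.
"""

# gas constant, kcal mol^-1 K^-1
R_GAS_KCAL: float = 1.98720425e-3

# Boltzmann constant, J K^-1
K_BOLTZMANN: float = 1.380649e-23

# Planck constant, J s
PLANCK_H: float = 6.62607015e-34

# transmission coefficient in the Eyring pre-factor (standard TST)
KAPPA: float = 1.0

# reporting temperature for "25 °C" tables, K
T_STANDARD: float = 298.15

# standard-state concentration for converting Ka to a free energy, M
C_STANDARD: float = 1.0
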