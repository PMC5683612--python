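"""Physical constants and shared unit conventions (kJ/mol, nm, K, amu, e)."""

#: Molar gas constant in kJ mol^-1 K^-1 (CODATA 2018).
GAS_CONSTANT_KJ: float = 8.314462618e-3

#: Default simulation temperature (K) for membrane-peptide systems.
DEFAULT_TEMPERATURE: float = 303.0

#: Repulsive floor of the Martini epsilon ladder (kJ/mol).
EPSILON_REPULSIVE: float = 2.0
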