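"""Physical constants used throughout (SI units)."""

#: hc in eV*m (CODATA: 1.23984193 eV*um)
HC_EV_M = 1.23984193e-6

#: classical electron radius (m)
R_E = 2.8179403e-15

#: Avogadro constant (1/mol)
N_A = 6.02214076e23
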