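"""Physical constants in the package's unit system (nm, kJ/mol, e, K)."""

#: Boltzmann constant, kJ mol^-1 K^-1.
BOLTZMANN = 0.0083144621

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2.
COULOMB = 138.935458
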