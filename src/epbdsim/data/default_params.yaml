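# Default EPBD parameter set.
#
# Morse depths/widths and the anharmonic stacking constants are the
# DNA-melting-fit PBD values of Campa & Giansanti (1998): D_AT = 0.05 eV,
# a_AT = 4.2 1/Angstrom for the two-hydrogen-bond A.T pair, D_GC = 0.075 eV,
# a_GC = 6.9 1/Angstrom for G.C, k = 0.025 eV/Angstrom^2, rho = 2, b = 0.35.
# The stacking table is keyed by the ordered dinucleotide step
# (base n-1, base n) and is uniform here; replace entries with a
# heterogeneous melting-derived table to make stacking sequence-specific.
morse_depth:
  AT: 0.05
  GC: 0.075
morse_width:
  AT: 4.2
  GC: 6.9
stacking_k:
  AA: 0.025
  AC: 0.025
  AG: 0.025
  AT: 0.025
  CA: 0.025
  CC: 0.025
  CG: 0.025
  CT: 0.025
  GA: 0.025
  GC: 0.025
  GG: 0.025
  GT: 0.025
  TA: 0.025
  TC: 0.025
  TG: 0.025
  TT: 0.025
stacking_rho: 2.0
stacking_b: 0.35
kB: 8.617333262e-5
y_min_bound: -2.0
y_max_bound: 20.0
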