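# Canonical leaching reaction set, one "label: equation" per line.
# Terms are separated by " + " (spaces required); charges are trailing
# signed integers (Fe+3); coefficients may be integers or fractions (1/2).
# "Me" is a placeholder divalent metal instantiated by Cu, Ni or Zn.
pyrite_O2: 2 FeS2 + 7 O2 + 2 H2O -> 2 Fe+2 + 4 SO4-2 + 4 H+1
ferrous_oxidation: 4 Fe+2 + O2 + 4 H+1 -> 4 Fe+3 + 2 H2O
pyrite_ferric: FeS2 + 14 Fe+3 + 8 H2O -> 15 Fe+2 + 2 SO4-2 + 16 H+1
metal_ferric: Me + 2 Fe+3 -> Me+2 + 2 Fe+2
metal_acid_O2: 2 Me + 2 H2SO4 + O2 -> 2 MeSO4 + 2 H2O
nickel_acid: Ni + 1/2 O2 + H2SO4 -> NiSO4 + H2O
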