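{
  "_comment": "Bondi-class van der Waals radii in Angstrom, keyed by element symbol. Crystal structures generally lack hydrogens; the slightly inflated C/N/O values act as a united-atom compromise. 'default' is used for unlisted elements only when allow_default is set.",
  "H": 1.2,
  "C": 1.7,
  "N": 1.55,
  "O": 1.52,
  "P": 1.8,
  "S": 1.8,
  "Se": 1.9,
  "F": 1.47,
  "Cl": 1.75,
  "Br": 1.85,
  "I": 1.98,
  "Zn": 1.39,
  "Fe": 1.4,
  "Mg": 1.73,
  "Ca": 1.9,
  "Na": 2.27,
  "K": 2.75,
  "default": 1.8
}
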