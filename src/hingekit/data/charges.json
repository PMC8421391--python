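{
  "_comment": "Formal charge sites per residue type for the screened-Coulomb model. 'atoms' lists the atom names whose centroid carries the formal charge (falling back through the list order if some are missing). Histidine is neutral by default; termini are not modelled.",
  "LYS": {"atoms": ["NZ"], "charge": 1},
  "ARG": {"atoms": ["NE", "NH1", "NH2"], "charge": 1, "fallback": ["CZ"]},
  "GLU": {"atoms": ["OE1", "OE2"], "charge": -1},
  "ASP": {"atoms": ["OD1", "OD2"], "charge": -1},
  "HIS": {"atoms": ["ND1", "NE2"], "charge": 0}
}
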