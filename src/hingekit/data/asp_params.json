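{
  "_comment": "Atomic solvation parameters (ASP), Eisenberg-McLachlan class, in kcal/(mol*A^2). G_solv = sum sigma(class) * ASA(atom). Positive sigma for apolar atoms means burying them is stabilizing. 'by_element' gives the default class per element; 'overrides' refine charged groups by (residue name, atom name).",
  "by_element": {
    "C": 0.016,
    "N": -0.006,
    "O": -0.006,
    "S": 0.021,
    "P": -0.006,
    "H": 0.0,
    "Zn": 0.0
  },
  "overrides": {
    "GLU": {"OE1": -0.024, "OE2": -0.024},
    "ASP": {"OD1": -0.024, "OD2": -0.024},
    "LYS": {"NZ": -0.05},
    "ARG": {"NE": -0.05, "NH1": -0.05, "NH2": -0.05}
  }
}
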