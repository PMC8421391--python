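{
  "_comment": "ERAP1 domain boundaries (UniProt Q9NZ08 numbering) as commonly drawn from the first crystal structures of the enzyme: domain I N-terminal beta-sandwich, domain II thermolysin-like catalytic domain, domain III beta-sandwich hinge, domain IV C-terminal HEAT-repeat bowl. These ranges are literature-derived, not authoritative for every construct; override the config for other numbering schemes.",
  "groups": {
    "I": [[46, 254]],
    "II": [[255, 529]],
    "III": [[530, 614]],
    "IV": [[615, 941]]
  },
  "hinge": "III",
  "proximal": "II",
  "distal": "IV"
}
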