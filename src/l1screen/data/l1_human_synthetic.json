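{
  "species_id": "human",
  "coordinate_convention": "1-based inclusive",
  "synthetic": true,
  "orf1_span": [
    908,
    1921
  ],
  "orf2_span": [
    1990,
    5817
  ],
  "domain_boundaries": {
    "EN": 239,
    "z": 490,
    "RT": 773,
    "Cys": null
  },
  "catalytic_residues": {
    "14": "N",
    "43": "E",
    "205": "D",
    "230": "H"
  },
  "nls_region": [
    382,
    385
  ],
  "nls_motif": "KKKR"
}
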