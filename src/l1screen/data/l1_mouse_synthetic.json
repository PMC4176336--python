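{
  "species_id": "mouse",
  "coordinate_convention": "1-based inclusive",
  "synthetic": true,
  "orf1_span": [
    1500,
    2702
  ],
  "orf2_span": [
    2801,
    6643
  ],
  "domain_boundaries": {
    "EN": 258,
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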