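{
  "version": "1.0",
  "comment": "Ideal backbone internal coordinates (Engh-Huber-style averages). Lengths in Angstrom, angles in degrees.",
  "bond_lengths": {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "CA-CB": 1.521
  },
  "bond_angles": {
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "N-CA-CB": 110.4
  },
  "torsions": {
    "C-N-CA-CB_improper": 122.6
  }
}
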