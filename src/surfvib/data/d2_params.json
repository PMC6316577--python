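{
  "comment": "Grimme DFT-D2 elemental parameters (2006 set): C6 in J nm^6 mol^-1, vdW radius r0 in Angstrom. s6 is the PBE global scale; d the damping steepness.",
  "version": "D2-2006",
  "s6": 0.75,
  "d": 20.0,
  "cutoff": 30.0,
  "elements": {
    "H":  {"C6": 0.14, "r0": 1.001},
    "C":  {"C6": 1.75, "r0": 1.452},
    "N":  {"C6": 1.23, "r0": 1.397},
    "O":  {"C6": 0.70, "r0": 1.342},
    "Si": {"C6": 9.23, "r0": 1.716}
  }
}
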