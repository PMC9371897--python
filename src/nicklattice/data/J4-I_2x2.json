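{
  "boundary": {
    "policy": "blunt"
  },
  "cols": 2,
  "connectivity": "square_grid",
  "mask": "all",
  "motif": {
    "root_length": 11,
    "stem_length": 10,
    "type": "J4"
  },
  "name": "J4-I_2x2",
  "rows": 2
}
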