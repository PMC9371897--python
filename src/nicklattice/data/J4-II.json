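{
  "boundary": {
    "policy": "blunt"
  },
  "cols": 6,
  "connectivity": "square_grid",
  "mask": "all",
  "motif": {
    "root_length": 13,
    "stem_length": 6,
    "type": "J4"
  },
  "name": "J4-II",
  "rows": 6
}
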