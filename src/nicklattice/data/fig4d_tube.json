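{
  "boundary": {
    "complementary": true,
    "overhang_length": 3,
    "policy": "overhang",
    "sides": [
      "E",
      "W"
    ]
  },
  "cols": 6,
  "connectivity": "square_grid",
  "mask": "all",
  "motif": {
    "root_length": 11,
    "stem_length": 10,
    "type": "J4"
  },
  "name": "fig4d_tube",
  "rows": 6
}
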