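{
  "boundary": {
    "policy": "blunt"
  },
  "cols": 7,
  "connectivity": "brick_wall",
  "mask": "all",
  "motif": {
    "root_length": 11,
    "stem_length": 10,
    "type": "J3"
  },
  "name": "J3",
  "rows": 6
}
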