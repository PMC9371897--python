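{
  "boundary": {
    "policy": "blunt"
  },
  "cols": 6,
  "connectivity": "dx_rows",
  "mask": "all",
  "motif": {
    "internal_nicks": 1,
    "root_length": 21,
    "root_role": "rigidity",
    "stem_length": 10,
    "stem_role": "sticky",
    "type": "DX"
  },
  "name": "DX-I",
  "rows": 6
}
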