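{
  "base": "J4-I",
  "carved_motifs": [
    [
      0,
      0
    ],
    [
      0,
      1
    ],
    [
      1,
      0
    ]
  ],
  "edges": [
    "e_h_r0c0",
    "e_h_r0c1",
    "e_h_r1c0",
    "e_v_r0c0",
    "e_v_r0c1",
    "e_v_r1c0"
  ],
  "mode": "edge_exclude",
  "name": "fig4c_mask",
  "target_motifs": [
    [
      0,
      2
    ],
    [
      0,
      3
    ],
    [
      0,
      4
    ],
    [
      0,
      5
    ],
    [
      1,
      1
    ],
    [
      1,
      2
    ],
    [
      1,
      3
    ],
    [
      1,
      4
    ],
    [
      1,
      5
    ],
    [
      2,
      0
    ],
    [
      2,
      1
    ],
    [
      2,
      2
    ],
    [
      2,
      3
    ],
    [
      2,
      4
    ],
    [
      2,
      5
    ],
    [
      3,
      0
    ],
    [
      3,
      1
    ],
    [
      3,
      2
    ],
    [
      3,
      3
    ],
    [
      3,
      4
    ],
    [
      3,
      5
    ],
    [
      4,
      0
    ],
    [
      4,
      1
    ],
    [
      4,
      2
    ],
    [
      4,
      3
    ],
    [
      4,
      4
    ],
    [
      4,
      5
    ],
    [
      5,
      0
    ],
    [
      5,
      1
    ],
    [
      5,
      2
    ],
    [
      5,
      3
    ],
    [
      5,
      4
    ],
    [
      5,
      5
    ]
  ]
}
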