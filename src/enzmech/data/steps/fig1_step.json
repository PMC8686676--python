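{
  "educt_gml": "graph [\n  node [ id h0 label \"C\" residue \"His#1\" ]\n  node [ id h1 label \"C\" residue \"His#1\" ]\n  node [ id h10 label \"N\" residue \"His#1\" ]\n  node [ id h11 label \"N\" residue \"His#1\" ]\n  node [ id h2 label \"C\" residue \"His#1\" ]\n  node [ id h3 label \"C\" residue \"His#1\" ]\n  node [ id h4 label \"H\" residue \"His#1\" ]\n  node [ id h5 label \"H\" residue \"His#1\" ]\n  node [ id h6 label \"H\" residue \"His#1\" ]\n  node [ id h7 label \"H\" residue \"His#1\" ]\n  node [ id h8 label \"H\" residue \"His#1\" ]\n  node [ id h9 label \"H\" residue \"His#1\" ]\n  node [ id m0 label \"C\" ]\n  node [ id m1 label \"O\" ]\n  node [ id m10 label \"H\" ]\n  node [ id m2 label \"O\" ]\n  node [ id m3 label \"C\" ]\n  node [ id m4 label \"C\" ]\n  node [ id m5 label \"H\" ]\n  node [ id m6 label \"H\" ]\n  node [ id m7 label \"H\" ]\n  node [ id m8 label \"H\" ]\n  node [ id m9 label \"H\" ]\n  node [ id s0 label \"C\" residue \"Ser#1\" ]\n  node [ id s1 label \"C\" residue \"Ser#1\" ]\n  node [ id s10 label \"H\" residue \"Ser#1\" ]\n  node [ id s11 label \"O\" residue \"Ser#1\" ]\n  node [ id s2 label \"C\" residue \"Ser#1\" ]\n  node [ id s3 label \"H\" residue \"Ser#1\" ]\n  node [ id s4 label \"H\" residue \"Ser#1\" ]\n  node [ id s5 label \"H\" residue \"Ser#1\" ]\n  node [ id s6 label \"H\" residue \"Ser#1\" ]\n  node [ id s7 label \"H\" residue \"Ser#1\" ]\n  node [ id s8 label \"H\" residue \"Ser#1\" ]\n  node [ id s9 label \"H\" residue \"Ser#1\" ]\n  edge [ source h0 target h1 label \"-\" ]\n  edge [ source h0 target h4 label \"-\" ]\n  edge [ source h0 target h5 label \"-\" ]\n  edge [ source h0 target h6 label \"-\" ]\n  edge [ source h1 target h11 label \"-\" ]\n  edge [ source h1 target h2 label \"=\" ]\n  edge [ source h2 target h10 label \"-\" ]\n  edge [ source h2 target h7 label \"-\" ]\n  edge [ source h3 target h10 label \"-\" ]\n  edge [ source h3 target h11 label \"=\" ]\n  edge [ source h3 target h8 label \"-\" ]\n  edge [ source h9 target h10 label \"-\" ]\n  edge [ source m0 target m1 label \"=\" ]\n  edge [ source m0 target m2 label \"-\" ]\n  edge [ source m0 target m4 label \"-\" ]\n  edge [ source m2 target m3 label \"-\" ]\n  edge [ source m3 target m5 label \"-\" ]\n  edge [ source m3 target m6 label \"-\" ]\n  edge [ source m3 target m7 label \"-\" ]\n  edge [ source m4 target m10 label \"-\" ]\n  edge [ source m4 target m8 label \"-\" ]\n  edge [ source m4 target m9 label \"-\" ]\n  edge [ source s0 target s1 label \"-\" ]\n  edge [ source s0 target s2 label \"-\" ]\n  edge [ source s0 target s3 label \"-\" ]\n  edge [ source s0 target s4 label \"-\" ]\n  edge [ source s1 target s5 label \"-\" ]\n  edge [ source s1 target s6 label \"-\" ]\n  edge [ source s1 target s7 label \"-\" ]\n  edge [ source s10 target s11 label \"-\" ]\n  edge [ source s2 target s11 label \"-\" ]\n  edge [ source s2 target s8 label \"-\" ]\n  edge [ source s2 target s9 label \"-\" ]\n]\n",
  "product_gml": "graph [\n  node [ id h0 label \"C\" residue \"His#1\" ]\n  node [ id h1 label \"C\" residue \"His#1\" ]\n  node [ id h10 label \"N\" residue \"His#1\" ]\n  node [ id h11 label \"N+\" residue \"His#1\" ]\n  node [ id h2 label \"C\" residue \"His#1\" ]\n  node [ id h3 label \"C\" residue \"His#1\" ]\n  node [ id h4 label \"H\" residue \"His#1\" ]\n  node [ id h5 label \"H\" residue \"His#1\" ]\n  node [ id h6 label \"H\" residue \"His#1\" ]\n  node [ id h7 label \"H\" residue \"His#1\" ]\n  node [ id h8 label \"H\" residue \"His#1\" ]\n  node [ id h9 label \"H\" residue \"His#1\" ]\n  node [ id m0 label \"C\" ]\n  node [ id m1 label \"O-\" ]\n  node [ id m10 label \"H\" ]\n  node [ id m2 label \"O\" ]\n  node [ id m3 label \"C\" ]\n  node [ id m4 label \"C\" ]\n  node [ id m5 label \"H\" ]\n  node [ id m6 label \"H\" ]\n  node [ id m7 label \"H\" ]\n  node [ id m8 label \"H\" ]\n  node [ id m9 label \"H\" ]\n  node [ id s0 label \"C\" residue \"Ser#1\" ]\n  node [ id s1 label \"C\" residue \"Ser#1\" ]\n  node [ id s10 label \"H\" residue \"Ser#1\" ]\n  node [ id s11 label \"O\" residue \"Ser#1\" ]\n  node [ id s2 label \"C\" residue \"Ser#1\" ]\n  node [ id s3 label \"H\" residue \"Ser#1\" ]\n  node [ id s4 label \"H\" residue \"Ser#1\" ]\n  node [ id s5 label \"H\" residue \"Ser#1\" ]\n  node [ id s6 label \"H\" residue \"Ser#1\" ]\n  node [ id s7 label \"H\" residue \"Ser#1\" ]\n  node [ id s8 label \"H\" residue \"Ser#1\" ]\n  node [ id s9 label \"H\" residue \"Ser#1\" ]\n  edge [ source h0 target h1 label \"-\" ]\n  edge [ source h0 target h4 label \"-\" ]\n  edge [ source h0 target h5 label \"-\" ]\n  edge [ source h0 target h6 label \"-\" ]\n  edge [ source h1 target h11 label \"-\" ]\n  edge [ source h1 target h2 label \"=\" ]\n  edge [ source h2 target h10 label \"-\" ]\n  edge [ source h2 target h7 label \"-\" ]\n  edge [ source h3 target h10 label \"-\" ]\n  edge [ source h3 target h11 label \"=\" ]\n  edge [ source h3 target h8 label \"-\" ]\n  edge [ source h9 target h10 label \"-\" ]\n  edge [ source m0 target m1 label \"-\" ]\n  edge [ source m0 target m2 label \"-\" ]\n  edge [ source m0 target m4 label \"-\" ]\n  edge [ source m2 target m3 label \"-\" ]\n  edge [ source m3 target m5 label \"-\" ]\n  edge [ source m3 target m6 label \"-\" ]\n  edge [ source m3 target m7 label \"-\" ]\n  edge [ source m4 target m10 label \"-\" ]\n  edge [ source m4 target m8 label \"-\" ]\n  edge [ source m4 target m9 label \"-\" ]\n  edge [ source s0 target s1 label \"-\" ]\n  edge [ source s0 target s2 label \"-\" ]\n  edge [ source s0 target s3 label \"-\" ]\n  edge [ source s0 target s4 label \"-\" ]\n  edge [ source s1 target s5 label \"-\" ]\n  edge [ source s1 target s6 label \"-\" ]\n  edge [ source s1 target s7 label \"-\" ]\n  edge [ source s10 target h11 label \"-\" ]\n  edge [ source s11 target m0 label \"-\" ]\n  edge [ source s2 target s11 label \"-\" ]\n  edge [ source s2 target s8 label \"-\" ]\n  edge [ source s2 target s9 label \"-\" ]\n]\n",
  "atom_map": [
    [
      "h0",
      "h0"
    ],
    [
      "h1",
      "h1"
    ],
    [
      "h10",
      "h10"
    ],
    [
      "h11",
      "h11"
    ],
    [
      "h2",
      "h2"
    ],
    [
      "h3",
      "h3"
    ],
    [
      "h4",
      "h4"
    ],
    [
      "h5",
      "h5"
    ],
    [
      "h6",
      "h6"
    ],
    [
      "h7",
      "h7"
    ],
    [
      "h8",
      "h8"
    ],
    [
      "h9",
      "h9"
    ],
    [
      "m0",
      "m0"
    ],
    [
      "m1",
      "m1"
    ],
    [
      "m10",
      "m10"
    ],
    [
      "m2",
      "m2"
    ],
    [
      "m3",
      "m3"
    ],
    [
      "m4",
      "m4"
    ],
    [
      "m5",
      "m5"
    ],
    [
      "m6",
      "m6"
    ],
    [
      "m7",
      "m7"
    ],
    [
      "m8",
      "m8"
    ],
    [
      "m9",
      "m9"
    ],
    [
      "s0",
      "s0"
    ],
    [
      "s1",
      "s1"
    ],
    [
      "s10",
      "s10"
    ],
    [
      "s11",
      "s11"
    ],
    [
      "s2",
      "s2"
    ],
    [
      "s3",
      "s3"
    ],
    [
      "s4",
      "s4"
    ],
    [
      "s5",
      "s5"
    ],
    [
      "s6",
      "s6"
    ],
    [
      "s7",
      "s7"
    ],
    [
      "s8",
      "s8"
    ],
    [
      "s9",
      "s9"
    ]
  ],
  "annotations": {
    "s0": "Ser#1",
    "s1": "Ser#1",
    "s2": "Ser#1",
    "s3": "Ser#1",
    "s4": "Ser#1",
    "s5": "Ser#1",
    "s6": "Ser#1",
    "s7": "Ser#1",
    "s8": "Ser#1",
    "s9": "Ser#1",
    "s10": "Ser#1",
    "s11": "Ser#1",
    "h0": "His#1",
    "h1": "His#1",
    "h2": "His#1",
    "h3": "His#1",
    "h4": "His#1",
    "h5": "His#1",
    "h6": "His#1",
    "h7": "His#1",
    "h8": "His#1",
    "h9": "His#1",
    "h10": "His#1",
    "h11": "His#1"
  },
  "flags": {
    "radical": false
  },
  "tags": [
    "proton transfer",
    "nucleophilic addition"
  ],
  "mechanism_id": "worked-example",
  "step_index": 1
}
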