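rule [
  ruleID "fig1_rule"
  mechanism "worked-example"
  process "proton transfer,nucleophilic addition"
  step "1"
  left [
    node [ id h11 label "N" ]
    node [ id m1 label "O" ]
    edge [ source m0 target m1 label "=" ]
    edge [ source s10 target s11 label "-" ]
  ]
  context [
    node [ id h0 label "C" ]
    node [ id h1 label "C" ]
    node [ id h10 label "N" ]
    node [ id h2 label "C" ]
    node [ id h3 label "C" ]
    node [ id h4 label "H" ]
    node [ id h5 label "H" ]
    node [ id h6 label "H" ]
    node [ id h7 label "H" ]
    node [ id h8 label "H" ]
    node [ id h9 label "H" ]
    node [ id m0 label "C" ]
    node [ id m2 label "O" ]
    node [ id m3 label "C" ]
    node [ id m4 label "C" ]
    node [ id s0 label "C" ]
    node [ id s1 label "C" ]
    node [ id s10 label "H" ]
    node [ id s11 label "O" ]
    node [ id s2 label "C" ]
    node [ id s3 label "H" ]
    node [ id s4 label "H" ]
    node [ id s5 label "H" ]
    node [ id s6 label "H" ]
    node [ id s7 label "H" ]
    node [ id s8 label "H" ]
    node [ id s9 label "H" ]
    edge [ source h0 target h1 label "-" ]
    edge [ source h0 target h4 label "-" ]
    edge [ source h0 target h5 label "-" ]
    edge [ source h0 target h6 label "-" ]
    edge [ source h1 target h11 label "-" ]
    edge [ source h1 target h2 label "=" ]
    edge [ source h10 target h2 label "-" ]
    edge [ source h10 target h3 label "-" ]
    edge [ source h10 target h9 label "-" ]
    edge [ source h11 target h3 label "=" ]
    edge [ source h2 target h7 label "-" ]
    edge [ source h3 target h8 label "-" ]
    edge [ source m0 target m2 label "-" ]
    edge [ source m0 target m4 label "-" ]
    edge [ source m2 target m3 label "-" ]
    edge [ source s0 target s1 label "-" ]
    edge [ source s0 target s2 label "-" ]
    edge [ source s0 target s3 label "-" ]
    edge [ source s0 target s4 label "-" ]
    edge [ source s1 target s5 label "-" ]
    edge [ source s1 target s6 label "-" ]
    edge [ source s1 target s7 label "-" ]
    edge [ source s11 target s2 label "-" ]
    edge [ source s2 target s8 label "-" ]
    edge [ source s2 target s9 label "-" ]
  ]
  right [
    node [ id h11 label "N+" ]
    node [ id m1 label "O-" ]
    edge [ source h11 target s10 label "-" ]
    edge [ source m0 target m1 label "-" ]
    edge [ source m0 target s11 label "-" ]
  ]
]
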