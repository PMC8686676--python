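# proton transfer from a hydroxyl oxygen to a neutral nitrogen base
rule [
  ruleID "pt_o_to_n"
  process "proton transfer"
  left [
    node [ id 0 label "O" ]
    node [ id 2 label "N" ]
    edge [ source 0 target 1 label "-" ]
  ]
  context [
    node [ id 1 label "H" ]
  ]
  right [
    node [ id 0 label "O-" ]
    node [ id 2 label "N+" ]
    edge [ source 1 target 2 label "-" ]
  ]
]
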