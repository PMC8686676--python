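# proton transfer from a protonated nitrogen back to an alkoxide/oxyanion
rule [
  ruleID "pt_n_to_o"
  process "proton transfer"
  left [
    node [ id 0 label "N+" ]
    node [ id 2 label "O-" ]
    edge [ source 0 target 1 label "-" ]
  ]
  context [
    node [ id 1 label "H" ]
  ]
  right [
    node [ id 0 label "N" ]
    node [ id 2 label "O" ]
    edge [ source 1 target 2 label "-" ]
  ]
]
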