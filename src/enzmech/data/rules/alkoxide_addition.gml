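# an alkoxide/hydroxide oxyanion adds to an ester carbonyl carbon
rule [
  ruleID "alkoxide_addition"
  process "nucleophilic addition"
  left [
    node [ id 0 label "O-" ]
    node [ id 2 label "O" ]
    edge [ source 1 target 2 label "=" ]
  ]
  context [
    node [ id 1 label "C" ]
    node [ id 3 label "O" ]
    edge [ source 1 target 3 label "-" ]
  ]
  right [
    node [ id 0 label "O" ]
    node [ id 2 label "O-" ]
    edge [ source 0 target 1 label "-" ]
    edge [ source 1 target 2 label "-" ]
  ]
]
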