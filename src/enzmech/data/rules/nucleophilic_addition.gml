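# concerted nucleophile activation and addition: a base nitrogen abstracts
# the hydroxyl proton while the oxygen attacks an ester carbonyl carbon
rule [
  ruleID "nucleophilic_addition"
  process "proton transfer,nucleophilic addition"
  left [
    node [ id 2 label "N" ]
    node [ id 4 label "O" ]
    edge [ source 0 target 1 label "-" ]
    edge [ source 3 target 4 label "=" ]
  ]
  context [
    node [ id 0 label "O" ]
    node [ id 1 label "H" ]
    node [ id 3 label "C" ]
    node [ id 5 label "O" ]
    edge [ source 3 target 5 label "-" ]
  ]
  right [
    node [ id 2 label "N+" ]
    node [ id 4 label "O-" ]
    edge [ source 1 target 2 label "-" ]
    edge [ source 0 target 3 label "-" ]
    edge [ source 3 target 4 label "-" ]
  ]
]
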