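# carboxylate base abstracts an alpha C-H; the enolate oxyanion forms
rule [
  ruleID "enolate_form"
  process "proton transfer,unimolecular elimination"
  left [
    node [ id 0 label "O-" ]
    node [ id 4 label "O" ]
    edge [ source 1 target 2 label "-" ]
    edge [ source 2 target 3 label "-" ]
    edge [ source 3 target 4 label "=" ]
  ]
  context [
    node [ id 1 label "H" ]
    node [ id 2 label "C" ]
    node [ id 3 label "C" ]
  ]
  right [
    node [ id 0 label "O" ]
    node [ id 4 label "O-" ]
    edge [ source 0 target 1 label "-" ]
    edge [ source 2 target 3 label "=" ]
    edge [ source 3 target 4 label "-" ]
  ]
]
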