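# tetrahedral oxyanion collapse: the C-O bond to the leaving-group oxygen
# breaks while a protonated nitrogen hands its proton to the leaving group
rule [
  ruleID "oxyanion_collapse"
  process "proton transfer,unimolecular elimination"
  left [
    node [ id 0 label "O-" ]
    node [ id 3 label "N+" ]
    edge [ source 0 target 1 label "-" ]
    edge [ source 1 target 2 label "-" ]
    edge [ source 3 target 4 label "-" ]
  ]
  context [
    node [ id 1 label "C" ]
    node [ id 2 label "O" ]
    node [ id 4 label "H" ]
    node [ id 5 label "C" ]
    edge [ source 2 target 5 label "-" ]
  ]
  right [
    node [ id 0 label "O" ]
    node [ id 3 label "N" ]
    edge [ source 0 target 1 label "=" ]
    edge [ source 2 target 4 label "-" ]
  ]
]
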