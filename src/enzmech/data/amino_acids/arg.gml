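graph [
  node [ id 0 label "C" ]
  node [ id 1 label "C" ]
  node [ id 2 label "H" ]
  node [ id 3 label "H" ]
  node [ id 4 label "H" ]
  node [ id 5 label "H" ]
  node [ id 6 label "H" ]
  node [ id 7 label "H" ]
  node [ id 8 label "H" ]
  node [ id 9 label "H" ]
  node [ id 10 label "N" ]
  node [ id 11 label "N" ]
  node [ id 12 label "N+" ]
  edge [ source 0 target 2 label "-" ]
  edge [ source 0 target 3 label "-" ]
  edge [ source 0 target 4 label "-" ]
  edge [ source 0 target 10 label "-" ]
  edge [ source 1 target 10 label "-" ]
  edge [ source 1 target 11 label "-" ]
  edge [ source 1 target 12 label "=" ]
  edge [ source 5 target 10 label "-" ]
  edge [ source 6 target 11 label "-" ]
  edge [ source 7 target 11 label "-" ]
  edge [ source 8 target 12 label "-" ]
  edge [ source 9 target 12 label "-" ]
]
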