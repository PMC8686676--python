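graph [
  node [ id 0 label "C" ]
  node [ id 1 label "C" ]
  node [ id 2 label "C" ]
  node [ id 3 label "C" ]
  node [ id 4 label "H" ]
  node [ id 5 label "H" ]
  node [ id 6 label "H" ]
  node [ id 7 label "H" ]
  node [ id 8 label "H" ]
  node [ id 9 label "H" ]
  node [ id 10 label "H" ]
  node [ id 11 label "H" ]
  node [ id 12 label "H" ]
  node [ id 13 label "H" ]
  node [ id 14 label "H" ]
  node [ id 15 label "N" ]
  edge [ source 0 target 1 label "-" ]
  edge [ source 0 target 2 label "-" ]
  edge [ source 0 target 4 label "-" ]
  edge [ source 0 target 5 label "-" ]
  edge [ source 1 target 3 label "-" ]
  edge [ source 1 target 6 label "-" ]
  edge [ source 1 target 7 label "-" ]
  edge [ source 2 target 8 label "-" ]
  edge [ source 2 target 9 label "-" ]
  edge [ source 2 target 10 label "-" ]
  edge [ source 3 target 11 label "-" ]
  edge [ source 3 target 12 label "-" ]
  edge [ source 3 target 15 label "-" ]
  edge [ source 13 target 15 label "-" ]
  edge [ source 14 target 15 label "-" ]
]
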