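# protonated imidazole ring (one N formally positive)
graph [
  node [ id 0 label "N+" ]
  node [ id 1 label "C" ]
  node [ id 2 label "N" ]
  node [ id 3 label "C" ]
  node [ id 4 label "C" ]
  edge [ source 0 target 1 label "=" ]
  edge [ source 1 target 2 label "-" ]
  edge [ source 2 target 3 label "-" ]
  edge [ source 3 target 4 label "=" ]
  edge [ source 4 target 0 label "-" ]
]
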