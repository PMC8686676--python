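graph [
  node [ id 0 label "C" ]
  node [ id 1 label "O" ]
  node [ id 2 label "O-" ]
  edge [ source 0 target 1 label "=" ]
  edge [ source 0 target 2 label "-" ]
]
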