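{
  "amino_acids": [
    {
      "label": "Ser",
      "name": "Ser",
      "file": "ser.gml"
    },
    {
      "label": "Cys",
      "name": "Cys",
      "file": "cys.gml"
    },
    {
      "label": "Thr",
      "name": "Thr",
      "file": "thr.gml"
    },
    {
      "label": "Asp",
      "name": "Asp",
      "file": "asp.gml"
    },
    {
      "label": "Glu",
      "name": "Glu",
      "file": "glu.gml"
    },
    {
      "label": "Lys",
      "name": "Lys",
      "file": "lys.gml"
    },
    {
      "label": "Tyr",
      "name": "Tyr",
      "file": "tyr.gml"
    },
    {
      "label": "Arg",
      "name": "Arg",
      "file": "arg.gml"
    },
    {
      "label": "His",
      "name": "His-t1",
      "file": "his_t1.gml"
    },
    {
      "label": "His",
      "name": "His-t2",
      "file": "his_t2.gml"
    }
  ]
}
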