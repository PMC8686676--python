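{
  "patterns": [
    {
      "name": "alcohol",
      "file": "alcohol.gml"
    },
    {
      "name": "aldehyde",
      "file": "aldehyde.gml"
    },
    {
      "name": "alkene",
      "file": "alkene.gml"
    },
    {
      "name": "alkoxide",
      "file": "alkoxide.gml"
    },
    {
      "name": "amide",
      "file": "amide.gml"
    },
    {
      "name": "ammonium",
      "file": "ammonium.gml"
    },
    {
      "name": "benzene",
      "file": "benzene.gml"
    },
    {
      "name": "carbonyl",
      "file": "carbonyl.gml"
    },
    {
      "name": "carboxyl_any",
      "file": "carboxyl_any.gml"
    },
    {
      "name": "carboxylate",
      "file": "carboxylate.gml"
    },
    {
      "name": "carboxylic_acid",
      "file": "carboxylic_acid.gml"
    },
    {
      "name": "ester",
      "file": "ester.gml"
    },
    {
      "name": "ether",
      "file": "ether.gml"
    },
    {
      "name": "guanidinium",
      "file": "guanidinium.gml"
    },
    {
      "name": "hydroxyl",
      "file": "hydroxyl.gml"
    },
    {
      "name": "imidazole_t1",
      "file": "imidazole_t1.gml"
    },
    {
      "name": "imidazole_t2",
      "file": "imidazole_t2.gml"
    },
    {
      "name": "imidazolium",
      "file": "imidazolium.gml"
    },
    {
      "name": "primary_amine",
      "file": "primary_amine.gml"
    },
    {
      "name": "thiol",
      "file": "thiol.gml"
    },
    {
      "name": "thiolate",
      "file": "thiolate.gml"
    },
    {
      "name": "water",
      "file": "water.gml"
    }
  ]
}
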