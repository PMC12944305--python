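{
  "comment": "Undesired-substructure SMARTS used both on fragments entering the library and on assembled molecules (where a junction bond may create the motif). The carbohydrate test (pyranose/furanose ring bearing >=2 hydroxyls) is ring-logic, not a single SMARTS; it is implemented in code and can be overridden by registering a pattern named 'carbohydrate' here.",
  "version": 1,
  "patterns": [
    {"name": "phosphate", "smarts": "[#15](~[OX1,OX2])~[OX1,OX2]"},
    {"name": "ester", "smarts": "[CX3](=[OX1])[OX2][#6]"},
    {"name": "acyclic_NN", "smarts": "[#7]!@[#7]"},
    {"name": "acyclic_NO", "smarts": "[#7]-!@[OX2]"},
    {"name": "acyclic_OO", "smarts": "[#8]-!@[#8]"}
  ]
}
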