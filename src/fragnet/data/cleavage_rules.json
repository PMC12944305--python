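{
  "comment": "Bond-cleavage SMARTS by fragmentation rule-set. In each pattern the bond that is cut is the bond between the first two mapped atoms. Ring bonds are never cut (!@). The 'brics' rule-set is not listed here: it delegates to the published BRICS bond finder.",
  "version": 1,
  "recap": [
    {"name": "amide", "smarts": "[C;$(C=O)]-;!@[N;!$(N=*)]"},
    {"name": "ester", "smarts": "[C;$(C=O)]-;!@[O;$(O[#6])]"},
    {"name": "amine", "smarts": "[N;!R;!$(N=*);!$(N[C,S]=[O,S,N])]-;!@[C;!$(C=*)]"},
    {"name": "ether", "smarts": "[#6]-;!@[O;D2;!$(O[C,S]=[O,S,N]);$(O[#6])]"},
    {"name": "olefin", "smarts": "[C;!R]=;!@[C;!R]"},
    {"name": "aromatic_n_aliphatic_c", "smarts": "[n]-;!@[C]"},
    {"name": "lactam_n_aliphatic_c", "smarts": "[N;R;$(N@[C;R]=O)]-;!@[C]"},
    {"name": "biaryl", "smarts": "[c]-;!@[c]"},
    {"name": "sulfonamide", "smarts": "[S;$(S(=O)=O)]-;!@[N]"}
  ],
  "scaffold_tree": [
    {"name": "ring_ring", "smarts": "[R]-;!@[R]"},
    {"name": "ring_linker", "smarts": "[R]-;!@[!R;!D1]"}
  ]
}
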