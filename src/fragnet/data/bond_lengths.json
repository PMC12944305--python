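{
  "comment": "Reference covalent bond lengths (angstrom) keyed by element.hybridization pair and bond order, derived from MMFF94-style force-field equilibrium values. Pairs are symmetric. 'fallback' entries are element-pair defaults used when no typed entry exists.",
  "version": 1,
  "bend_ideal_deg": {"sp3": 109.5, "sp2": 120.0, "aromatic": 120.0, "sp": 180.0},
  "typed": [
    ["C.sp3", "C.sp3", 1, 1.53],
    ["C.sp3", "C.sp2", 1, 1.50],
    ["C.sp3", "C.aromatic", 1, 1.51],
    ["C.sp3", "C.sp", 1, 1.47],
    ["C.sp2", "C.sp2", 1, 1.46],
    ["C.sp2", "C.sp2", 2, 1.33],
    ["C.sp2", "C.aromatic", 1, 1.47],
    ["C.aromatic", "C.aromatic", 1, 1.48],
    ["C.sp2", "C.sp", 1, 1.43],
    ["C.sp2", "C.sp", 2, 1.31],
    ["C.sp", "C.sp", 1, 1.37],
    ["C.sp", "C.sp", 3, 1.20],
    ["C.sp3", "N.sp3", 1, 1.47],
    ["C.sp3", "N.sp2", 1, 1.45],
    ["C.sp3", "N.aromatic", 1, 1.45],
    ["C.sp2", "N.sp3", 1, 1.40],
    ["C.sp2", "N.sp2", 1, 1.36],
    ["C.sp2", "N.sp2", 2, 1.28],
    ["C.aromatic", "N.sp3", 1, 1.40],
    ["C.aromatic", "N.sp2", 1, 1.40],
    ["C.aromatic", "N.aromatic", 1, 1.41],
    ["C.sp", "N.sp", 3, 1.16],
    ["C.sp3", "O.sp3", 1, 1.42],
    ["C.sp2", "O.sp3", 1, 1.36],
    ["C.aromatic", "O.sp3", 1, 1.36],
    ["C.sp2", "O.sp2", 2, 1.22],
    ["N.sp3", "N.sp3", 1, 1.45],
    ["N.sp2", "N.sp2", 1, 1.40],
    ["N.sp2", "N.sp2", 2, 1.25],
    ["N.sp3", "O.sp3", 1, 1.40],
    ["O.sp3", "O.sp3", 1, 1.48],
    ["C.sp3", "S.sp3", 1, 1.81],
    ["C.sp2", "S.sp3", 1, 1.76],
    ["C.aromatic", "S.sp3", 1, 1.77],
    ["N.sp3", "S.sp3", 1, 1.70],
    ["S.sp3", "S.sp3", 1, 2.05]
  ],
  "fallback": [
    ["C", "C", 1, 1.51],
    ["C", "C", 2, 1.33],
    ["C", "C", 3, 1.20],
    ["C", "N", 1, 1.43],
    ["C", "N", 2, 1.28],
    ["C", "N", 3, 1.16],
    ["C", "O", 1, 1.40],
    ["C", "O", 2, 1.22],
    ["C", "S", 1, 1.80],
    ["N", "N", 1, 1.45],
    ["N", "N", 2, 1.25],
    ["N", "O", 1, 1.40],
    ["N", "S", 1, 1.70],
    ["O", "O", 1, 1.48],
    ["O", "S", 1, 1.57],
    ["S", "S", 1, 2.05],
    ["C", "F", 1, 1.35],
    ["C", "Cl", 1, 1.77],
    ["C", "Br", 1, 1.94],
    ["C", "I", 1, 2.14]
  ]
}
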