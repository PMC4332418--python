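{
  "comment": "Empirical side-chain configurational entropy weights (kcal/mol at 300 K) per unit change in relative side-chain exposure; configurable, Pickett-style scale.",
  "ALA": 0.0,
  "ARG": 2.03,
  "ASN": 1.57,
  "ASP": 1.25,
  "CYS": 0.55,
  "GLN": 2.11,
  "GLU": 1.81,
  "GLY": 0.0,
  "HIS": 0.96,
  "ILE": 0.89,
  "LEU": 0.78,
  "LYS": 1.94,
  "MET": 1.61,
  "PHE": 0.58,
  "PRO": 0.0,
  "SER": 1.71,
  "THR": 1.63,
  "TRP": 0.97,
  "TYR": 0.99,
  "VAL": 0.51
}
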