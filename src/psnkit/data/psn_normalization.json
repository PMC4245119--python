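{
  "_comment": "Default per-residue-type interaction-strength normalization constants N_i used in I_ij = 100 * n_ij / sqrt(N_i * N_j). Editable; residue types missing from this table fall back to the residue heavy-atom count.",
  "ALA": 55.76,
  "ARG": 93.79,
  "ASN": 73.41,
  "ASP": 75.15,
  "CYS": 54.95,
  "GLN": 78.13,
  "GLU": 78.83,
  "GLY": 47.31,
  "HIS": 83.74,
  "ILE": 67.97,
  "LEU": 72.25,
  "LYS": 69.61,
  "MET": 69.26,
  "PHE": 93.31,
  "PRO": 51.33,
  "SER": 59.39,
  "THR": 63.71,
  "TRP": 106.70,
  "TYR": 100.72,
  "VAL": 62.37
}
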