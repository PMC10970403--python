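{
  "comment": "Clustal conservation groups: a column is ':' when all residues fall in one strong group, '.' when in one weak group.",
  "strong": ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"],
  "weak": ["CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SDEQN", "NDEQHK", "NEQHRK", "FVLIM", "HFY"]
}
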