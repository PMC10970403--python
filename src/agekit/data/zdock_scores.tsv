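# External macromolecular-docking scoring-function values of the selected
# glycated-albumin / RAGE V-domain conformations (higher = more favourable).
# Consumed as opaque input data; the scoring function is never computed here.
site	zdock_score
Lys64	741.0
Lys73	888.3
Lys137	1011.2
Lys233	1059.3
Lys262	963.0
Lys317	1034.8
Lys378	878.7
Lys525	828.5
Lys573	895.5
Lys574	828.6
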