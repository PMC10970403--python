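# Published distances (A) between the C2-domain monomers in the 21 pairwise
# receptor-dimer models assembled from the seven specific glycated-albumin /
# V-domain complexes.  overlap=1 marks pairings whose V-domain monomers
# superimpose (the dimer cannot form).  Transcribed from the printed table;
# used only as expected values for cross-checks, never as a computation input.
site_a	site_b	c2_distance	overlap
Lys64	Lys137	229	0
Lys64	Lys233	185	0
Lys64	Lys262	188	0
Lys64	Lys378	176	0
Lys64	Lys525	243	0
Lys64	Lys573	116	0
Lys137	Lys233	191	0
Lys137	Lys262	213	0
Lys137	Lys378	243	0
Lys137	Lys525	41	0
Lys137	Lys573	162	1
Lys233	Lys262	24	1
Lys233	Lys378	164	1
Lys233	Lys525	191	0
Lys233	Lys573	223	0
Lys262	Lys378	114	0
Lys262	Lys525	213	0
Lys262	Lys573	238	0
Lys378	Lys525	228	0
Lys378	Lys573	227	0
Lys525	Lys573	177	0
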