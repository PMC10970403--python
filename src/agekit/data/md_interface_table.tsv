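# Published per-complex interface summary of the ten glycated-albumin / RAGE V-domain
# complexes after 100 ns of molecular dynamics: per-side counts of atoms forming
# short-range (3.5 A) contacts, the contacting residues on each side, and the specific
# contacts (SB salt bridge, HB hydrogen bond, PP pi-pi) with lifetimes as a percent of
# the simulation length.  Transcribed from the printed table; consumed as input data.
site	ghsa_atoms	ghsa_residues	rage_atoms	rage_residues	specific_contacts
Lys64	63	Glu48, Glu45, Lys64, Asp72, Thr76, Val77, Glu86, Cys91, Val92, Lys93, Gln94, Glu95	73	Arg48, Lys52, Glu59, Ala60, Trp61, Lys62, Arg98, Lys107	Glu45-Arg48 (SB, 100%); Glu48-Lys107 (SB, 30%); Lys64-Lys52 (SB, 80%); Lys64-Arg98 (SB, 95%); Asp72-Lys52 (SB, 80%); Glu86-Lys62 (SB, 50%); Glu95-Lys52 (SB, 70%)
Lys73	66	Glu37, Asp38, Val40, Lys41, Glu45, Lys73, Glu82, Val122, Thr125, Ala126, Asp129, Thr133	68	Gln24, Asn25, Lys37, Lys39, Arg114, Arg116	Glu37-Gln24 (HB, 40%); Asp38-Lys37 (SB, 40%); Glu45-Lys39 (SB, 65%); Lys73-Lys39 (SB, 30%); Glu82-Lys37 (SB, 40%); Asp129-Arg114 (SB, 85%); Asp129-Arg116 (SB, 60%)
Lys137	68	Glu37, Pro35, Asp38, Glu82, Thr83, Tyr84, Arg114, Val122, Thr125, Lys137	58	Lys44, Gln47, Arg48, Gln67, Met102, Arg104, Asn105, Glu108	Glu37-Arg48 (SB, 5%); Asp38-Arg104 (SB, 50%); Asp38-Gln47 (HB, 10%); Glu82-Lys44 (SB, 5%); Glu83-Asn105 (HB, 5%); Arg114-Glu108 (SB, 20%); Lys137-Arg48 (SB, 95%)
Lys233	104	His3, Lys4, Glu6, His9, Glu208, Lys212, Glu230, Lys233, Thr236, Asp237, Lys240, Glu252, Asp255, Asp256, Asp259, Lys262, Glu266, Asn267	103	Gln24, Val35, Lys37, Lys39, Lys43, Leu79, Pro80, Asn81, Lys107, Glu108, Thr109, Lys110, Ser111, Tyr113	His3-Asn81 (HB, 95%); Glu6-Lys83 (SB, 95%); Glu208-Lys107 (SB, 95%); Lys212-Glu108 (SB, 75%); Glu230-Lys110 (SB, 20%); Lys233-Lys39 (SB, 80%); Lys233-Ser111 (HB, 65%); Lys233-Tyr113 (HB, 40%); Thr236-Glu108 (HB, 60%); Asp237-Lys39 (SB, 80%); Glu252-Lys43 (SB, 98%); Asp255-Lys37 (SB, 60%); Asp256-Lys37 (SB, 60%); Asp259-Lys37 (SB, 60%)
Lys262	65	Asp13, Lys233, Thr236, Asp237, Glu252, Asp255, Asp256, Asp259, Lys262, Tyr263, Glu266	54	Lys39, Lys43, Lys44, Asn105, Gly106, Lys107, Glu108	Asp13-Lys43 (SB, 90%); Lys233-Glu108 (SB, 90%); Thr236-Asn105 (HB, 90%); Glu252-Lys44 (SB, 70%); Asp255-Lys43 (SB, 90%); Asp256-Lys44 (SB, 75%); Asp259-Lys107 (SB, 10%); Lys262-Lys39 (SB, 10%); Tyr263-Glu108 (HB, 90%); Glu266-Lys39 (SB, 70%)
Lys317	21	Ala229, Glu230, Lys233, Asp259	27	Gln24, Lys39, Lys107, Ser111	Glu230-Lys39 (SB, 2%); Lys233-Ser111 (HB, 10%); Asp259-Lys107 (SB, 70%)
Lys378	116	Glu297, Ala300, Pro303, Ala306, Ala307, Glu311, Asp340, Phe374, Asp375, Lys378, Val381, Gln385, Pro441, Glu442, Met446	109	Arg29, Glu32, Pro33, Leu34, Val35, Lys37, Lys39, Pro46, Arg48, Arg77, Val78, Pro80, Asn81, Phe85	Glu297-Lys39 (SB, 50%); Glu311-Arg29 (SB, 80%); Phe374-Phe85 (PP, 20%); Asp375-Arg77 (SB, 95%); Lys378-Arg77 (SB, 20%); Gln385-Pro80 (HB, 60%); Glu442-Arg48 (SB, 30%)
Lys525	101	Glu119, Asp173, Ala175, Ala176, Leu179, Pro180, Asp183, Glu184, Arg186, Glu518, Lys519, Glu520, Lys525, Gln522, Lys560, Asp562	109	Lys39, Gly40, Pro42, Lys44, Arg48, Lys52, Arg57, Glu59, Met102, Arg104, Asn105, Gly106, Lys107, Glu108, Thr109	Glu119-Lys107 (SB, 80%); Asp173-Lys39 (SB, 90%); Asp183-Asn105 (HB, 60%); Glu184-Lys44 (SB, 65%); Glu518-Lys52 (SB, 80%); Lys519-Glu108 (SB, 90%); Glu520-Arg104 (SB, 80%); Lys525-Arg48 (SB, 5%); Asp562-Arg57 (SB, 90%)
Lys573	47	Pro113, Arg114, Leu115, Val116, Ala511, Asp512, Glu565, Thr566, Ala569, Lys573	59	Arg29, Pro33, Pro66, Gln67, Arg77, Leu79, Phe85	Val116-Pro66 (HB, 5%); Asp512-Arg77 (SB, 50%); Lys573-Arg29 (SB, 30%); Glu565-Arg77 (SB, 70%)
Lys574	142	Phe36, Glu37, Tyr84, Leu112, Arg114, Leu115, Val116, Asp121, Val122, Thr125, Asp129, Lys137, Tyr140, Glu505, Thr508, His510, Ala511, Glu565, Phe568, Ala569, Lys573	139	Gly31, Glu32, Pro33, Val35, Lys37, Lys43, Pro45, Pro46, Arg48, Gln67, Ser74, Arg77, Leu79, Pro80, Phe85, Arg104	Asp129-Arg104 (SB, 80%); Asp121-Lys43 (SB, 20%); Glu37-Arg48 (SB, 60%); Glu565-Lys37 (SB, 90%); Glu505-Arg77 (SB, 70%); Phe36-Gln67 (HB, 30%); Tyr140-Gln67 (HB, 60%); Lys573-Gly31 (HB, 80%); Arg114-Ser74 (HB, 10%)
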