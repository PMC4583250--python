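# The 24 study variants predicted deleterious (SIFT) and probably damaging
# (PolyPhen), with their published annotations. counts = carrier counts among
# the 436 sequenced genomes. conserved = strictly conserved across the study's
# nine-species vertebrate alignment.
position	ref	alt	rsid	mitomap	counts	conserved	gene	codon_change	aa_change
3388	C	A	.	Known	1	No	MT-ND1	Cta/Ata	L/M
6237	C	A	.	Known	2	No	MT-CO1	Ctg/Atg	L/M
6489	C	A	rs28461189	Known	3	Yes	MT-CO1	Ctc/Atc	L/I
7941	A	G	.	Known	1	Yes	MT-CO2	aAc/aGc	N/S
7964	T	C	.	Known	1	No	MT-CO2	Ttc/Ctc	F/L
7976	G	A	.	Known	1	Yes	MT-CO2	Ggc/Agc	G/S
8563	A	G	.	Known	1	No	MT-ATP6	Aca/Gca	T/A
8839	G	A	.	Known	2	Yes	MT-ATP6	Gcc/Acc	A/T
8920	G	A	.	Known	1	No	MT-ATP6	Ggc/Agc	G/S
9010	G	A	.	Known	1	Yes	MT-ATP6	Gct/Act	A/T
9448	A	G	.	Known	1	Yes	MT-CO3	tAc/tGc	Y/C
9500	C	A	.	Unknown	1	No	MT-CO3	ttC/ttA	F/L
9577	T	C	.	Unknown	1	Yes	MT-CO3	cTa/cCa	L/P
9903	T	C	rs199999390	Known	1	Yes	MT-CO3	Ttt/Ctt	F/L
11087	T	C	.	Known	1	Yes	MT-ND4	Ttc/Ctc	F/L
12634	A	G	.	Known	3	Yes	MT-ND5	Atc/Gtc	I/V
12923	G	T	.	Known	1	No	MT-ND5	tGa/tTa	W/L
13129	C	T	.	Known	1	Yes	MT-ND5	Ccc/Tcc	P/S
13973	A	T	.	Known	1	No	MT-ND5	cAa/cTa	Q/L
14180	T	C	.	Known	2	No	MT-ND6	tAt/tGt	Y/C
14484	T	C	.	Known	2	No	MT-ND6	Atg/Gtg	M/V
14769	A	G	rs28357679	Known	2	Yes	MT-CYB	aAc/aGc	N/S
15218	A	G	rs2853506	Known	10	No	MT-CYB	Aca/Gca	T/A
15773	G	A	.	Known	1	Yes	MT-CYB	Gta/Ata	V/M
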