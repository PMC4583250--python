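# The 35 study variants (including 3 indels) absent from the MITOMAP catalog,
# with their published annotations. Category tokens are normalised to the
# package vocabulary; "-" marks fields the study left empty.
position	ref	alt	conserved	gene	effect	sift	polyphen
393	T	A	No	-	-	-	-
1713	A	G	No	MT-RNR2	non_coding	-	-
1807	T	C	No	MT-RNR2	non_coding	-	-
2150	T	TA	Yes	MT-RNR2	non_coding	-	-
2156	A	AT	No	MT-RNR2	non_coding	-	-
3385	A	T	No	MT-ND1	missense	deleterious	possibly_damaging
4875	C	T	No	MT-ND2	synonymous	-	-
5573	A	G	No	MT-TW	non_coding	-	-
5746	GA	G	No	-	-	-	-
6113	A	T	No	MT-CO1	synonymous	-	-
6200	C	T	No	MT-CO1	synonymous	-	-
6569	C	T	No	MT-CO1	synonymous	-	-
6608	C	T	No	MT-CO1	synonymous	-	-
6812	A	G	No	MT-CO1	synonymous	-	-
7004	A	G	No	MT-CO1	synonymous	-	-
7366	C	T	Yes	MT-CO1	missense	tolerated	benign
8263	C	T	No	MT-CO2	synonymous	-	-
8465	C	T	No	MT-ATP8	missense	tolerated	probably_damaging
8673	A	G	No	MT-ATP6	synonymous	-	-
9138	C	T	No	MT-ATP6	synonymous	-	-
9370	A	T	No	MT-CO3	missense	tolerated	benign
9500	C	A	No	MT-CO3	missense	deleterious	probably_damaging
9577	T	C	Yes	MT-CO3	missense	deleterious	probably_damaging
9873	C	A	No	MT-CO3	missense	tolerated	probably_damaging
9890	A	G	No	MT-CO3	synonymous	-	-
10030	C	T	No	MT-TG	non_coding	-	-
10094	C	A	No	MT-ND3	synonymous	-	-
12098	C	T	No	MT-ND4	synonymous	-	-
12266	A	G	No	MT-TL2	non_coding	-	-
13380	C	T	No	MT-ND5	synonymous	-	-
13792	C	T	No	MT-ND5	synonymous	-	-
13806	C	T	No	MT-ND5	synonymous	-	-
15620	C	T	Yes	MT-CYB	missense	deleterious	possibly_damaging
16229	T	A	No	-	-	-	-
16454	C	T	No	-	-	-	-
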