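# Human mtDNA gene model: standard rCRS (NC_012920.1) coordinates and strands.
# `length` is the published per-gene length used as the enrichment denominator
# (carried verbatim; it is not recomputed from the coordinates).
# `variant_count`, `rg_printed`, `rw_printed`: per-gene distinct-variant counts and
# enrichment rates as published for the 436-genome targeted mtDNA study.
symbol	biotype	start	end	strand	length	variant_count	rg_printed	rw_printed
MT-RNR1	Mt_rRNA	648	1601	+	955	34	35.6	1.07
MT-RNR2	Mt_rRNA	1671	3229	+	1561	57	37.2	0.64
MT-ND1	protein_coding	3307	4262	+	957	58	60.6	0.27
MT-ND2	protein_coding	4470	5511	+	1043	64	61.4	0.62
MT-CO1	protein_coding	5904	7445	+	1543	98	63.5	0.29
MT-CO2	protein_coding	7586	8269	+	685	44	64.2	0.11
MT-ATP8	protein_coding	8366	8572	+	208	15	72.1	0.12
MT-ATP6	protein_coding	8527	9207	+	682	59	86.5	0.92
MT-CO3	protein_coding	9207	9990	+	785	60	76.4	0.23
MT-ND3	protein_coding	10059	10404	+	347	24	69.2	0.30
MT-ND4L	protein_coding	10470	10766	+	298	20	67.1	0.23
MT-ND4	protein_coding	10760	12137	+	1379	85	61.6	0.46
MT-ND5	protein_coding	12337	14148	+	1813	134	73.9	0.27
MT-ND6	protein_coding	14149	14673	-	526	26	49.4	0.24
MT-CYB	protein_coding	14747	15887	+	1142	96	84.1	0.91
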