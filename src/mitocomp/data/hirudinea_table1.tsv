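# Genomic characteristics of 25 Hirudinea mitogenomes (GenBank records).
# Percentages are the published 1-decimal values; skews are the published
# 3-decimal values. partial=yes marks records published as incomplete.
# Whitmania laevis 1 prints G as "160." in the source table (evident typo);
# the value is kept verbatim and the row is flagged unverifiable.
species	accession	size_bp	pT	pC	pA	pG	at_pct	at_skew	gc_skew	partial
Torix tukubana	OL779256	14814	38.4	14.5	35.2	11.9	73.6	-0.043	-0.098	no
Acanthobdella peledina	MZ562997.1	18528	35.2	19.0	34.7	11.1	69.9	-0.007	-0.262	no
Codonobdella sp. IK-2021	MZ202177.1	14486	38.9	12.3	36.6	12.2	75.5	-0.030	-0.004	no
Erpobdella japonica	MF358688.1	14725	37.0	14.9	35.2	13.0	72.2	-0.025	-0.068	no
Erpobdella octoculata	KC688270.1	14407	40.6	12.5	30.9	15.9	71.5	-0.136	0.120	no
Erpobdella sp. JP-2021	MW435182.1	15469	36.0	17.4	33.8	12.8	69.8	-0.032	-0.152	no
Erpobdella testacea	MT584166.1	14495	36.7	14.5	36.4	12.4	73.1	-0.004	-0.078	yes
Glossiphonia concolor	MT628565.1	14548	39.2	13.1	35.5	12.2	74.7	-0.050	-0.036	yes
Haemadipsa crenata	MW711186.1	14725	42.4	10.9	34.4	12.3	76.8	-0.104	0.060	no
Haemadipsa tianmushana	MZ189977.1	14625	42.8	10.5	35.1	11.6	77.9	-0.099	0.050	no
Haementeria acuecueyetzin	MT683771.1	14985	38.9	14.9	34.8	11.4	73.7	-0.056	-0.133	no
Haementeria officinalis	LT159848.1	14849	39.0	15.1	34.3	11.7	73.3	-0.064	-0.127	yes
Hemiclepsis yangtzenensis	MN106285.1	14984	37.7	15.0	35.2	12.1	72.9	-0.034	-0.107	no
Hirudinaria manillensis	KC688268.1	14470	40.7	12.2	31.4	15.8	72.1	-0.129	0.129	no
Hirudo medicinalis	KU672396.1	14729	42.8	10.7	33.4	13.2	76.2	-0.123	0.105	yes
Hirudo nipponia	KC667144.1	14414	40.9	11.9	31.7	15.5	72.6	-0.127	0.131	no
Hirudo verbana	KU672397.1	14604	43.2	10.5	33.7	12.7	76.9	-0.124	0.095	yes
Ozobranchus jantseanus	KY861060.1	14864	37.4	14.9	35.0	12.6	72.4	-0.033	-0.084	no
Placobdella lamothei	LT159849.1	15190	36.4	18.0	31.7	13.9	68.1	-0.069	-0.129	no
Placobdella parasitica	LT159850.1	14909	37.8	15.5	34	12.7	71.8	-0.053	-0.099	yes
Whitmania acranulata	MK347500.1	14468	40.8	12.1	30.8	16.3	71.6	-0.140	0.148	no
Whitmania laevis 1	KC688269.1	14433	41.2	12.0	30.8	160.	72.0	-0.144	0.143	no
Whitmania laevis 2	KM655839.1	14442	41.9	11.1	31.1	15.9	73.0	-0.148	0.178	no
Whitmania pigra	EU304459.1	14426	41.3	11.8	30.8	16.1	72.1	-0.146	0.154	no
Zeylanicobdella arugamensis	KY474378.1	16161	43.7	10.4	35.5	10.3	79.2	-0.104	-0.005	no
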