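#genome_id=OL779256
#length=14814
token	start	end	strand	start_codon	stop_codon	anticodon
cox1	1	1537	+	ATG	T--
trnN	1538	1601	+			GTT
cox2	1602	2279	+	ATG	TAA
trnD	2281	2344	+			GTC
atp8	2345	2503	+	ATG	TAG
trnY	2502	2567	+			GTA
trnG	2566	2626	+			TCC
cox3	2624	3404	+	ATA	T--
trnQ	3405	3473	+			TTG
nad6	3475	3945	+	ATG	TAA
cob	3938	5074	+	ATG	TAA
trnW	5091	5154	+			TCA
atp6	5156	5860	+	ATG	TAA
trnR	5859	5926	+			TCG
CR	5927	6328	+
trnH	6329	6392	+			GTG
nad5	6393	8094	+	ATG	T--
trnF	8095	8157	+			GAA
trnE	8158	8216	+			TTC
trnP	8218	8281	+			TGG
trnT	8282	8343	+			TGT
nad4l	8344	8637	+	ATG	TAA
nad4	8631	9965	+	ATG	TAG
trnC	9964	10027	+			GCA
trnM	10028	10089	+			CAT
rrnS	10090	10824	+
trnV	10825	10887	+			TAC
rrnL	10888	12047	+
trnL1	12048	12107	+			TAG
trnA	12108	12167	+			TGC
trnS2	12167	12233	+			TGA
trnL2	12234	12294	+			TAA
nad1	12295	13233	+	ATG	TAA
trnI	13239	13300	+			GAT
trnK	13301	13365	+			TTT
nad3	13366	13719	+	ATG	TAG
trnS1	13717	13782	+			TCT
nad2	13784	14788	+	ATT	TAA
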