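name	category	strand	start	end	spacer	start_codon	stop_codon	anticodon
trnI	tRNA	J	1	66	5	.	.	GAT
trnM	tRNA	J	72	138	-3	.	.	CAT
nad2	PCG	J	139	1161	0	ATA	TAA	.
CR_ATR	CR_part	J	1162	2552	0	.	.	.
CR_TR	CR_part	J	2553	4281	33	.	.	.
trnQ	tRNA	N	4315	4383	35	.	.	TTG
trnW	tRNA	J	4419	4484	-1	.	.	TCA
trnC	tRNA	N	4484	4547	2	.	.	GCA
trnY	tRNA	N	4550	4616	16	.	.	GTA
cox1	PCG	J	4633	6148	0	TCT	T	.
trnL_UUR	tRNA	J	6149	6212	2	.	.	TAA
cox2	PCG	J	6215	6905	0	ATG	T	.
trnK	tRNA	J	6906	6975	-1	.	.	CTT
trnD	tRNA	J	6975	7042	0	.	.	GTC
atp8	PCG	J	7043	7207	-7	ATC	TAA	.
atp6	PCG	J	7201	7875	2	ATG	TAA	.
cox3	PCG	J	7878	8678	0	ATG	TAA	.
trnG	tRNA	J	8679	8742	0	.	.	TCC
nad3	PCG	J	8743	9096	6	ATC	TAA	.
trnA	tRNA	J	9103	9170	-1	.	.	TGC
trnR	tRNA	J	9170	9232	4	.	.	TCG
trnN	tRNA	J	9237	9302	0	.	.	GTT
trnS_AGN	tRNA	J	9303	9369	0	.	.	GCT
trnE	tRNA	J	9370	9435	-2	.	.	TTC
trnF	tRNA	N	9434	9496	0	.	.	GAA
nad5	PCG	N	9497	11213	0	ATA	T	.
trnH	tRNA	N	11214	11278	0	.	.	GTG
nad4	PCG	N	11279	12614	-7	ATG	T	.
nad4L	PCG	N	12608	12907	1	ATA	TAA	.
trnT	tRNA	J	12909	12972	-1	.	.	TGT
trnP	tRNA	N	12972	13040	0	.	.	TGG
nad6	PCG	J	13041	13558	0	CTG	TA	.
cob	PCG	J	13559	14693	0	ATG	T	.
trnS_UCN	tRNA	J	14694	14762	161	.	.	TGA
nad1	PCG	N	14924	15862	3	ATT	TAG	.
trnL_CUN	tRNA	N	15866	15928	-1	.	.	TAG
rrnL	rRNA	N	15928	17230	-2	.	.	.
trnV	tRNA	N	17229	17300	0	.	.	TAC
rrnS	rRNA	N	17301	18083	50	.	.	.
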