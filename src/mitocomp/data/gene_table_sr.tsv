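name	category	strand	start	end	spacer	start_codon	stop_codon	anticodon
trnI	tRNA	J	1	66	5	.	.	GAT
trnM	tRNA	J	72	138	0	.	.	CAT
nad2	PCG	J	139	1161	0	ATA	TAA	.
CR_ATR	CR_part	J	1162	2547	0	.	.	.
CR_TR	CR_part	J	2548	3419	33	.	.	.
trnQ	tRNA	N	3453	3521	36	.	.	TTG
trnW	tRNA	J	3558	3623	-1	.	.	TCA
trnC	tRNA	N	3623	3687	3	.	.	GCA
trnY	tRNA	N	3691	3757	16	.	.	GTA
cox1	PCG	J	3774	5289	0	TCT	T	.
trnL_UUR	tRNA	J	5290	5353	2	.	.	TAA
cox2	PCG	J	5356	6045	1	ATG	TAA	.
trnK	tRNA	J	6047	6116	-1	.	.	CTT
trnD	tRNA	J	6116	6183	0	.	.	GTC
atp8	PCG	J	6184	6348	-7	ATC	TAA	.
atp6	PCG	J	6342	7015	0	ATG	TA	.
cox3	PCG	J	7016	7815	0	ATG	TA	.
trnG	tRNA	J	7816	7880	0	.	.	TCC
nad3	PCG	J	7881	8234	7	ATC	TAA	.
trnA	tRNA	J	8242	8308	-1	.	.	TGC
trnR	tRNA	J	8308	8370	4	.	.	TCG
trnN	tRNA	J	8375	8440	0	.	.	GTT
trnS_AGN	tRNA	J	8441	8507	0	.	.	GCT
trnE	tRNA	J	8508	8573	-2	.	.	TTC
trnF	tRNA	N	8572	8634	0	.	.	GAA
nad5	PCG	N	8635	10351	0	ATA	T	.
trnH	tRNA	N	10352	10416	0	.	.	GTG
nad4	PCG	N	10417	11752	-7	ATG	T	.
nad4L	PCG	N	11746	12045	10	ATA	TAA	.
trnT	tRNA	J	12056	12119	-1	.	.	TGT
trnP	tRNA	N	12119	12187	0	.	.	TGG
nad6	PCG	J	12188	12705	0	TTG	TA	.
cob	PCG	J	12706	13840	0	ATG	T	.
trnS_UCN	tRNA	J	13841	13908	94	.	.	TGA
nad1	PCG	N	14003	14941	3	ATT	TAG	.
trnL_CUN	tRNA	N	14945	15007	0	.	.	TAG
rrnL	rRNA	N	15008	16307	0	.	.	.
trnV	tRNA	N	16308	16378	0	.	.	TAC
rrnS	rRNA	N	16379	17159	50	.	.	.
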