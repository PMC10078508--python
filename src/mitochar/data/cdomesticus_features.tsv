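name	strand	start	stop	start_codon	stop_codon
trnI	J	1	65	-	-
trnQ	N	142	74	-	-
trnM	J	150	215	-	-
nad2	J	237	1238	ATC	TAA
trnW	J	1238	1304	-	-
trnC	N	1362	1297	-	-
trnY	N	1435	1368	-	-
cox1	J	1437	2981	ATT	TAA
trnL2	J	2996	3062	-	-
cox2	J	3081	3747	ATA	T--
trnK	J	3748	3818	-	-
trnD	J	3819	3885	-	-
atp8	J	3886	4044	ATA	TAA
atp6	J	4038	4718	ATG	TAA
cox3	J	4718	5506	ATG	TAA
trnG	J	5511	5574	-	-
nad3	J	5575	5928	ATA	TAG
trnA	J	5928	5989	-	-
trnR	J	5993	6057	-	-
trnN	J	6059	6125	-	-
trnS1	J	6126	6192	-	-
trnE	J	6193	6255	-	-
trnF	N	6322	6257	-	-
nad5	N	8048	6323	ATG	T--
trnH	N	8113	8050	-	-
nad4	N	9461	8124	GTG	TAG
nad4l	N	9742	9455	ATG	TAA
trnT	J	9749	9812	-	-
trnP	N	9877	9813	-	-
nad6	J	9892	10368	ATA	TAA
cytb	J	10369	11502	ATG	TAG
trnS2	J	11501	11573	-	-
nad1	N	12535	11597	ATG	TAG
trnL1	N	12605	12538	-	-
rrnL	N	13929	12564	-	-
trnV	N	13979	13912	-	-
rrnS	N	14784	13980	-	-
d-loop	J	14785	15655	-	-
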