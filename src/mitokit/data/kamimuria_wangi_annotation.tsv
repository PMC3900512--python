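name	feature_class	start	end	strand	length	start_codon	stop_codon	ign
tRNA-Ile	tRNA	1	68	J	68
tRNA-Gln	tRNA	69	137	N	69			0
tRNA-Met	tRNA	139	207	J	69			1
ND2	PCG	208	1245	J	1038	ATG	TAA	0
tRNA-Trp	tRNA	1245	1311	J	67			-1
tRNA-Cys	tRNA	1304	1372	N	69			-8
tRNA-Tyr	tRNA	1372	1437	N	66			-1
COI	PCG	1397	2983	J	1587	ATA	TAA	-41
tRNA-Leu(UUR)	tRNA	2939	3004	J	66			-45
COII	PCG	3010	3705	J	686	ATG	TAA	56
tRNA-Lys	tRNA	3706	3776	J	71			0
tRNA-Asp	tRNA	3778	3846	J	69			1
ATP8	PCG	3856	4005	J	150	ATA	TAA	9
ATP6	PCG	3999	4676	J	678	ATG	TAA	-7
COIII	PCG	4676	5464	J	789	ATG	TAA	-1
tRNA-Gly	tRNA	5467	5533	J	67			2
ND3	PCG	5534	5887	J	354	ATT	TAA	0
tRNA-Ala	tRNA	5889	5953	J	65			1
tRNA-Arg	tRNA	5954	6017	J	64			0
tRNA-Asn	tRNA	6018	6084	J	67			0
tRNA-Ser(AGN)	tRNA	6085	6151	J	67			0
tRNA-Glu	tRNA	6152	6217	J	66			0
tRNA-Phe	tRNA	6224	6289	N	66			6
ND5	PCG	6273	8021	N	1749	ATG	TAA	-17
tRNA-His	tRNA	8022	8089	N	68			0
ND4	PCG	8091	9455	N	1365	ATG	TAG	1
ND4L	PCG	9449	9745	N	297	ATG	TAA	-7
tRNA-Thr	tRNA	9748	9813	J	66			2
tRNA-Pro	tRNA	9814	9880	N	67			0
ND6	PCG	9882	10397	J	516	ATG	TAA	1
CYTB	PCG	10397	11536	J	1140	ATG	TAG	-1
tRNA-Ser(UCN)	tRNA	11535	11604	J	70			-2
ND1	PCG	11558	12541	N	984	ATA	TAA	-47
tRNA-Leu(CUN)	tRNA	12570	12636	N	67			28
lrRNA	rRNA	12638	13982	N	1345			1
tRNA-Val	tRNA	13991	14061	N	71			8
srRNA	rRNA	14062	14928	N	867			0
CR	control_region	14929	16179	J	1251			0
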