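cohort	chrom	start	end	z_score	length	genes
RE	1	32671406	32673183	-3.78	1777	IQCC
RE	1	43296070	43317484	-6.52	21414	ERMAP;ZNF691
RE	1	53320120	53329849	-3.94	9729	ZYG11A
RE	1	55586222	55591447	-4.46	5225	USP24
RE	1	115137047	115168530	-3.13	31483	DENND2C
RE	1	150252003	150259252	-3.3	7249	C1orf54;CIART
RE	1	153658548	153662047	-3.44	3499	NPR1
RE	1	160061571	160064997	-4.46	3426	IGSF8
RE	1	249144392	249212591	-3.25	68199	PGBD2;ZNF692
RE	2	44502637	44539912	-4.48	37275	SLC3A1
RE	3	4403776	4562816	-3.79	159040	ITPR1;ITPR1-AS1;SUMF1
RE	4	169362457	169393930	-3.01	31473	DDX60L
RE	5	71519462	71533975	-5.36	14513	MRPS27
RE	5	75858199	75914495	-3.32	56296	F2RL2;IQGAP2
RE	5	96506883	96518935	-4.44	12052	RIOK2
RE	5	118965402	118970803	-4.73	5401	FAM170A
RE	5	140482462	140531165	-3.11	48703	PCDHB3;PCDHB4;PCDHB5;PCDHB6
RE	6	31777772	31779777	-3.97	2005	HSPA1L
RE	6	33693196	33703280	-6.64	10084	IP6K3
RE	6	44143759	44151705	-3.58	7946	CAPN11
RE	6	116441989	116442904	-5.26	915	COL10A1;NT5DC1
RE	7	74197233	74212576	-3.34	15343	GTF2IRD2;NCF1
RE	7	100146395	100153393	-4.98	6998	AGFG2
RE	8	82571539	82752251	-3.13	180712	CHMP4C;IMPA1;SLC10A5;SNX16;ZFAND1
RE	8	146028239	146033207	-4.62	4968	ZNF517
RE	9	35800178	35801935	-4.58	1757	NPR2
RE	9	140243513	140250835	-3.24	7322	EXD3
RE	10	5920045	5926074	-5.17	6029	ANKRD16
RE	10	49383834	49420140	-4.44	36306	FRMPD2
RE	11	2549103	2606577	-3.38	57474	KCNQ1
RE	11	4903092	4929495	-4.46	26403	OR51A7;OR51T1
RE	11	7727796	7818510	-3.74	90714	OR5P2;OVCH2
RE	11	17533429	17546119	-3.17	12690	USH1C
RE	11	47600393	47608426	-5.11	8033	FAM180B;KBTBD4;NDUFS3
RE	11	59189760	59211596	-3.31	21836	OR5A1;OR5A2
RE	11	64977256	64981526	-6.72	4270	CAPN1;SLC22A20
RE	12	6625993	6627159	-5.01	1166	NCAPD2
RE	12	130922883	130927235	-3.85	4352	RIMBP2
RE	14	54863694	55907289	-3.32	1043595	ATG14;CDKN3;CGRRF1;CNIH1;DLGAP5;FBXO34;GCH1;GMFB;LGALS3;MAPK1IP1L;MIR4308;SAMD4A;SOCS4;TBPL2;WDHD1
RE	14	77302503	77327178	-3.27	24675	LRRC74A
RE	14	92900208	92920437	-4.01	20229	SLC24A4
RE	15	23811123	28525396	-4.21	4714273	ATP10A;GABRA5;GABRB3;GABRG3;GABRG3-AS1;HERC2;IPW;LINC00929;LOC100128714;MAGEL2;MIR4715;MKRN3;NDN;NPAP1;OCA2;PWAR1;PWAR4;PWAR5;PWARSN;PWRN1;PWRN2;PWRN3;PWRN4;SNORD107;SNORD108;SNORD109A;SNORD109B;SNORD115-1;SNORD115-10;SNORD115-11;SNORD115-12;SNORD115-13
RE	15	29346087	32460550	-4.57	3114463	APBA2;ARHGAP11B;FAM7A;NA7;DKFZP434L187;FAM189A1;FAN1;GOLGA8H;GOLGA8J;GOLGA8R;GOLGA8T;HERC2P10;KLF13;LOC100288637;LOC283710;MIR211;MTMR10;NDNL2;OTUD7A;TJP1;TRPM1;ULK4P1;ULK4P2;ULK4P3
RE	16	9856958	10032248	-5.26	175290	GRIN2A
RE	16	70560498	70573138	-4.22	12640	SF3B3;SNORD111;SNORD111B
RE	17	7010272	7017572	-3.43	7300	ASGR2
RE	17	10403892	10632442	-3.09	228550	ADPRM;MAGOH2P;MYH1;MYH2;MYH3;MYHAS;SCO1;TMEM220
RE	17	38346658	38350074	-4.63	3416	MIR6867;RAPGEFL1
RE	17	73623470	73661285	-4.39	37815	RECQL5;SMIM5;SMIM6
RE	17	76967650	76970921	-4.45	3271	LGALS3BP
RE	18	30873076	30928981	-3.86	55905	CCDC178
RE	19	9014087	9054377	-4.25	40290	MUC16
RE	19	14673265	14677779	-4.49	4514	NDUFB7;TECR
RE	19	14854191	14884892	-3.24	30701	ADGRE2
RE	19	35862216	35941102	-3.7	78886	FFAR2;LINC01531
RE	19	45447959	45465365	-5.89	17406	APOC2;APOC4;APOC4-APOC2;CLPTM1
RE	19	51175236	51192575	-3.33	17339	SHANK1
RE	19	52271871	52327971	-3.68	56100	FPR2;FPR3
RE	20	39830726	39831937	-3.5	1211	ZHX3
RE	20	44806537	44845668	-4.27	39131	CDH22
RE	20	54823759	54824900	-8.62	1141	MC3R
GGE	1	76779478	77094515	-4.34	315037	ST6GALNAC3
GGE	1	169510234	169511641	-4.49	1407	F5
GGE	2	166852481	166872273	-3.02	19792	LOC102724058;SCN1A
GGE	3	10331397	10335915	-4.04	4518	GHRL;GHRLOS
GGE	5	21751815	21854929	-6.45	103114	CDH12
GGE	6	43320067	43323250	-3.68	3183	ZNF318
GGE	7	13971097	14028735	-5.88	57638	ETV1
GGE	7	121651161	121652685	-3.43	1524	PTPRZ1
GGE	7	146471346	146829615	-4.41	358269	CNTNAP2;LOC101928700
GGE	7	150501839	150558285	-3.04	56446	AOC1;TMEM176A
GGE	8	2944572	3045513	-6.06	100941	CSMD1
GGE	8	144391574	144400286	-4.33	8712	TOP1MT
GGE	9	21350268	21409671	-3.7	59403	IFNA13;IFNA2;IFNA6;IFNA8
GGE	9	97080895	97090973	-5.74	10078	NUTM2F
GGE	9	113189903	113550109	-7.57	360206	MUSK;SVEP1
GGE	10	20432177	20506529	-3.39	74352	PLXDC2
GGE	10	55568487	55582740	-4.38	14253	PCDH15
GGE	10	90524124	90534348	-5.32	10224	LIPN
GGE	10	116919814	117026498	-3.09	106684	ATRNL1
GGE	11	26568916	26587286	-3.41	18370	ANO3;MUC15
GGE	11	40136003	40137868	-3.76	1865	LRRC4C
GGE	11	60531165	60621186	-4.85	90021	CCDC86;MS4A10;MS4A15;PTGDR2
GGE	11	72465895	72794788	-3.31	328893	ATG16L2;FCHSD2;MIR4459;MIR4692;STARD10
GGE	11	124844950	124858018	-5.07	13068	CCDC15
GGE	12	40749853	41463875	-4.27	714022	CNTN1;LRRK2;MUC19
GGE	12	53073535	53086673	-3.42	13138	KRT1;KRT77
GGE	12	56825208	56827994	-5.15	2786	TIMELESS
GGE	12	91445072	91450028	-3.85	4956	KERA
GGE	13	23777841	24895857	-3.6	1118016	ANKRD20A19P;C1QTNF9;C1QTNF9B;C1QTNF9B-AS1;LINC00327;MIPEP;MIR2276;SACS;SACS-AS1;SGCG;SPATA13;SPATA13-AS1;TNFRSF19
GGE	16	20471400	20498025	-7.68	26625	ACSM2A
GGE	16	56659681	56693111	-4.59	33430	MT1A;MT1B;MT1DP;MT1E;MT1F;MT1JP;MT1M
GGE	16	61747707	61859108	-3.57	111401	CDH8
GGE	16	89804176	89849549	-4.26	45373	FANCA;ZNF276
GGE	17	36453091	36485777	-3.98	32686	GPR179;MRPL45
GGE	17	62850638	62856934	-4.31	6296	LRRC37A3
GGE	18	43496355	43604681	-3.89	108326	EPG5;PSTPIP2
GGE	19	1056280	1061916	-3.36	5636	ABCA7
GGE	19	9270761	9272102	-4.04	1341	ZNF317
GGE	19	37309563	37619956	-3.24	310393	ZNF345;ZNF420;ZNF568;ZNF790;ZNF790-AS1;ZNF829
GGE	19	58386121	58420835	-3.08	34714	ZNF417;ZNF814
GGE	20	2463808	2465032	-3.21	1224	ZNF343
GGE	20	22562576	23016658	-3.9	454082	FOXA2;LINC01384;SSTR4
GGE	20	58440579	58444005	-3.3	3426	SYCP2
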