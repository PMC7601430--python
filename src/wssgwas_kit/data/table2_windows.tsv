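trait	chrom	start_mb	end_mb	gv_percent	members	member_types
BT	2	0.35	1.28	2.16	LOC104971094;LOC107132231;LOC107132232;LOC784948;LGSN;OCA2;LOC783772;LOC100301143;HERC2;LOC104971093;TRNAE-CUC;NIPA1;NIPA2;LOC107132230;CYFIP1;TUBGCP5;TRNAE-UUC;CCDC115;IMP4;PTPN18	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
BT	2	72.46	73.83	1.11	INHBB;LOC781979;LOC104971258;GLI2;LOC104971259;LOC100335292;TRNAL-CAA;TFCP2L1;CLASP1;NIFK;TSN	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
BT	7	39.69	40.83	2.59	HK3;UIMC1;LOC510252;LOC100141185;LOC101905975;LOC784341;LOC533921;LOC782447;TRNAR-CCU;ZNF346;FGFR4;LOC100336707;LOC540197;RAB24;PRELID1;MXD3;LMAN2;RGS14;SLC34A1;PFN3;F12;GRK6;PRR7;DBN1;PDLIM7;DOK3;LOC104969157;DDX41;FAM193B;LOC509184;LOC100139419;TMED9;B4GALT7;LOC107132625;N4BP3;RMND5B;LOC101905866;NHP2;HNRNPAB;PHYKPL;COL23A1	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
BT	11	60.34	61.55	1.69	FAM161A;CCT4;COMMD1;B3GNT2;TMEM17;EHBP1;OTX1	gene;gene;gene;gene;gene;gene;gene
BT	13	40.02	41.40	1.08	CFAP61;INSM1;RALGAPA2;LOC104973781;LOC104973782;KIZ;LOC100140493;XRN2;NKX2-4;NKX2-2;LOC614124;PAX1	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
BT	16	34.80	35.91	1.08	LOC100297170;PLD5;LOC104974409;LOC104974410;BECN2;MAP1LC3C;EXO1;WDR64;LOC101907876	gene;gene;gene;gene;gene;gene;gene;gene;gene
CW	7	58.66	60.49	1.91	PRELID2;LOC107132647;LOC100138092;LOC788619;GRXCR2;SH3RF2;PLAC8L1;LARS;RBM27;POU4F3;TCERG1;GPR151;PPP2R2B;TRNAC-GCA;STK32A	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
CW	9	62.93	64.58	1.98	TRNAE-UUC;LOC100336843;AKIRIN2;ORC3;RARS2;SLC35A1;CFAP206;C9H6orf163;SMIM8;LOC104969583;GJB7;LOC107132774;ZNF292;LOC509829;CGA;HTR1E	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
CW	14	11.23	12.26	1.04	ASAP1;FAM49B;GSDMC	gene;gene;gene
CW	14	16.55	17.80	4.46	NSMCE2;KIAA0196;SQLE;ZNF572;MTSS1;NDUFB9;TATDN1;LOC104968469;RNF139;TRMT12;LOC531462;TMEM65;FER1L6;LOC101907615;FAM91A1;ANXA13	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
CW	14	17.85	19.46	2.0	LOC100848930;FBXO32;WDYHV1;ATAD2;ZHX1;C14H8orf76;FAM83A;TRNAM-CAU;LOC104974006;TBC1D31;DERL1;ZHX2;LOC104974007;LOC100139328	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
CW	14	22.09	23.61	4.31	SNTG1;LOC614437;PCMTD1;LOC101906226;LOC104974020;ST18;LOC100141260;LOC101906592;FAM150A;RB1CC1;LOC104974017;NPBWR1;OPRK1;ATP6V1H;RGS20	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
CW	14	24.58	25.33	17.66	XKR4;TMEM68;TGS1;LYN;RPS20;MOS;PLAG1;CHCHD7;SDR16C5;SDR16C6;PENK;LOC101907667	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
CW	14	25.36	26.15	2.43	LOC101907667;IMPAD1;FAM110B	gene;gene;gene
CW	14	29.43	30.44	3.75	NKAIN3;LOC107133118;GGH;TTPA;YTHDF3;LOC101907975	gene;gene;gene;gene;gene;gene
CW	14	30.54	32.16	1.3	MIR124A-2;BHLHE22;CYP7B1;LOC104974032;ARMC1;MTFR1;LOC104974034;PDE7A;LOC101902754;LOC100299601;LOC104974036;DNAJC5B;TRNAY-GUA;TRNAA-AGC;TRIM55	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
CW	14	32.25	33.90	1.43	CRH;LOC790324;ZSCAN5B;RRS1;ADHFE1;C14H8orf46;MYBL1;VCPIP1;SGK3;LOC104974037;MCMDC2;LOC784087;LOC100847363;TCF24;PPP1R42;COPS5;CSPP1;ARFGEF1;TRNAC-GCA;CPA6;LOC101902584	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
EMA	1	127.77	128.74	2.27	GK5;TFDP2;LOC101903974;LOC511302;ATP1B3;GRK7;RNF7;LOC104968752;RASA2;LOC100294923;ZBTB38;LOC107131348;LOC104971030;LOC104971031;PXYLP1;LOC104971032	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
EMA	6	0.1	1.03	1.0	APELA;LOC101905490;LOC513842;LOC101907917	gene;gene;gene;gene
EMA	6	54.52	55.64	1.11		
EMA	9	57.18	58.10	2.22	TRNAC-ACA;LOC782527;EPHA7	gene;gene;gene
EMA	14	22.09	23.61	1.75	SNTG1;LOC614437;PCMTD1;LOC101906226;LOC104974020;ST18;LOC100141260;LOC101906592;FAM150A;RB1CC1;LOC104974017;NPBWR1;OPRK1;ATP6V1H;RGS20	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
EMA	14	24.58	25.33	7.98	XKR4;TMEM68;TGS1;LYN;RPS20;MOS;PLAG1;CHCHD7;SDR16C5;SDR16C6;PENK;LOC101907667	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
EMA	19	48.90	50.02	1.0	LOC100140873;TEX2;TRNAG-UCC;LOC104975109;LOC101902037;PECAM1;MILR1;POLG2;DDX5;MIR3064;CEP95;SMURF2;TRNAE-CUC;KPNA2;TRNAR-CCG;C19H17orf58;BPTF;TRNAE-UUC;NOL11;TRNAS-AGA;PITPNC1;LOC101905668	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
MS	5	95.87	97.74	2.24	ATF7IP;LOC100139060;GRIN2B;EMP1;GSG1;FAM234B;HEBP1;GPRC5D;GPRC5A;DDX47;APOLD1;CDKN1B;LOC101901926;GPR19;CREBL2;LOC101902028;LOC107132517;DUSP16	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
MS	14	5.01	5.69	1.0	LOC100850800;COL22A1;FAM135B	gene;gene;gene
MS	23	30.27	31.28	2.03	ZNF389;ZSCAN16;ZNF165;OR2B6;HIST1H2BB;HIST1H2AG;bta-mir-2379;ZNF184;ZNF391;POM121L2;PRSS16;HIST1H2BN;ZNF322;ABT1	gene;gene;gene;gene;gene;gene;miRNA;gene;gene;gene;gene;gene;gene;gene
MS	27	16.11	17.15	1.28	LOC101905556;LOC101905700;ZFP42;TRNAG-UCC;TRIML2;TRNAF-AAA;TRIML1;LOC507011	gene;gene;gene;gene;gene;gene;gene;gene
MS	27	19.17	20.48	1.46	MICU3;FGF20;LOC104976064;TRNAC-ACA;MSR1;LOC104976066;TUSC3	gene;gene;gene;gene;gene;gene;gene
YW	2	42.77	43.75	1.71	LOC785568;LOC615401;ARL6IP6;TRNAY-GUA;PRPF40A;FMNL2;LOC101902790	gene;gene;gene;gene;gene;gene;gene
YW	6	37.26	38.45	1.36	FAM13A;LOC104972724;LOC100847719;HERC3;NAP1L5;PYURF;PIGY;HERC5;HERC6;PPM1K;ABCG2;LOC781421;PKD2;SPP1;MEPE;IBSP;LOC104972726	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
YW	6	39.50	40.67	2.68	LOC782905	gene
YW	6	44.67	45.42	1.14	PPARGC1A	gene
YW	6	48.80	49.97	2.3	LOC107132565	gene
YW	10	50.75	51.96	1.56	LOC107132854;FAM81A;MYO1E;CCNB2;RNF111;SLTM;FAM63B;LOC533308;ADAM10;LIPC;LOC101904602;LOC101903685;TRNAE-UUC	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
YW	14	16.55	17.80	1.7	NSMCE2;KIAA0196;SQLE;ZNF572;MTSS1;NDUFB9;TATDN1;LOC104968469;RNF139;TRMT12;LOC531462;TMEM65;FER1L6;LOC101907615;FAM91A1;ANXA13	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
YW	14	22.09	23.61	2.54	SNTG1;LOC614437;PCMTD1;LOC101906226;LOC104974020;ST18;LOC100141260;LOC101906592;FAM150A;RB1CC1;LOC104974017;NPBWR1;OPRK1;ATP6V1H;RGS20	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
YW	14	24.58	25.33	9.96	XKR4;TMEM68;TGS1;LYN;RPS20;MOS;PLAG1;CHCHD7;SDR16C5;SDR16C6;PENK;LOC101907667	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
YW	14	25.36	26.15	1.74	LOC101907667;IMPAD1;FAM110B	gene;gene;gene
YW	14	29.43	30.44	2.64	NKAIN3;LOC107133118;GGH;TTPA;YTHDF3;LOC101907975	gene;gene;gene;gene;gene;gene
YW	14	30.54	32.16	2.62	MIR124A-2;BHLHE22;CYP7B1;LOC104974032;ARMC1;MTFR1;LOC104974034;PDE7A;LOC101902754;LOC100299601;LOC104974036;DNAJC5B;TRNAY-GUA;TRNAA-AGC;TRIM55	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
YW	14	32.25	33.90	1.43	CRH;LOC790324;ZSCAN5B;RRS1;ADHFE1;C14H8orf46;MYBL1;VCPIP1;SGK3;LOC104974037;MCMDC2;LOC784087;LOC100847363;TCF24;PPP1R42;COPS5;CSPP1;ARFGEF1;TRNAC-GCA;CPA6;LOC101902584	gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene;gene
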