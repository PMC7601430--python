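gene	in_window_table
ABT1	true
ATF7IP	true
ATP6V1H	true
B3GNT2	true
C14H8orf46	true
C19H17orf58	true
CCDC115	true
CDKN1B	true
CGA	true
CLASP1	true
DERL1	true
EXO1	true
FAM135B	true
FAM234B	true
FAM83A	true
FAM91A1	true
GRK7	true
HEBP1	true
NIFK	true
NIPA1	true
NKAIN3	true
NSMCE2	true
PPARGC1A	true
PPM1L	false
PPP1R42	true
PRELID1	true
PRELID2	true
PXYLP1	true
RALGAPA2	true
RNF111	true
RNF7	true
SGK3	true
SLC31A1	false
SLTM	true
SMURF2	true
ST18	true
STK32A	true
TFDP2	true
TMEM68	true
TRIM55	true
ZHX1	true
ZNF346	true
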