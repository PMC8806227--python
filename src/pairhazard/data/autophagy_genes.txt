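# 127 autophagy-related human gene symbols (candidate list for pair construction)
APOL1
ARNT
ARSA
ARSB
ATF4
ATF6
ATG4B
ATG4D
ATIC
BAG1
BAG3
BAK1
BAX
BCL2L1
BECN1
BID
BIRC5
BIRC6
BNIP3
BNIP3L
CANX
CAPN1
CAPN2
CAPNS1
CASP1
CASP3
CASP4
CASP8
CCL2
CD46
CDKN1A
CDKN1B
CDKN2A
CHMP2B
CHMP4B
CLN3
CTSB
CTSD
CX3CL1
CXCR4
DAPK1
DDIT3
DLC1
DNAJB1
DNAJB9
DRAM1
EDEM1
EEF2
EEF2K
EGFR
EIF2AK2
EIF4EBP1
ERBB2
ERN1
FAS
FKBP1A
FKBP1B
FOS
FOXO1
FOXO3
GAA
GABARAPL1
GAPDH
GOPC
HDAC1
HDAC6
HGS
HIF1A
HSP90AB1
HSPA5
HSPA8
HSPB8
IKBKE
ITGA3
ITGA6
ITGB1
ITGB4
KIF5B
KLHL24
LAMP1
LAMP2
MAP1LC3A
MAP1LC3B
MAPK1
MAPK3
MAPK8IP1
MTOR
MYC
NAMPT
NBR1
NCKAP1
NFE2L2
NFKB1
NPC1
P4HB
PARP1
PEA15
PELP1
PEX14
PEX3
PIK3R4
PINK1
PPP1R15A
PRKAR1A
PRKCD
PTK6
RAB24
RAB33B
RB1
RB1CC1
RGS19
SERPINA1
SESN2
SIRT1
SPHK1
SQSTM1
TMEM74
TNFSF10
TP53
TP53INP2
TSC2
TUSC1
ULK1
ULK2
VAMP3
VEGFA
WIPI1
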