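symbol	category	alias
IRE1	ER_stress	ERN1
PERK	ER_stress	EIF2AK3
ATF6	ER_stress
ATF4	ER_stress
XBP1	ER_stress
HSPA5	ER_stress	BIP
DDIT3	ER_stress	CHOP
EDEM1	ER_stress
HERPUD1	ER_stress
DNAJC3	ER_stress	P58IPK
PPP1R15A	ER_stress	GADD34
ATF3	ER_stress
CALR	ER_stress
CANX	ER_stress
ASK1	oxidative_stress	MAP3K5
JNK	oxidative_stress	MAPK8
P38ALPHA	oxidative_stress	MAPK14
NFE2L2	oxidative_stress	NRF2
KEAP1	oxidative_stress
SOD1	oxidative_stress
SOD2	oxidative_stress
CAT	oxidative_stress
GPX1	oxidative_stress
TXN	oxidative_stress
TXNRD1	oxidative_stress
GSR	oxidative_stress
HMOX1	oxidative_stress
NQO1	oxidative_stress
CASP3	executioner_caspase
CASP6	executioner_caspase
CASP7	executioner_caspase
INS	INS_related
PDX1	INS_related
MAFA	INS_related
NEUROD1	INS_related
NKX6-1	INS_related
NKX2-2	INS_related
GCK	INS_related
SLC2A2	INS_related	GLUT2
ABCC8	INS_related	SUR1
KCNJ11	INS_related
GLP1R	INS_related
UCN3	INS_related
IAPP	INS_related
PCSK1	INS_related
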