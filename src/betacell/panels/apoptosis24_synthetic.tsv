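symbol	category	alias
RIPK1	apoptosis_pathway
RAIDD	apoptosis_pathway	CRADD
TNFR1	apoptosis_pathway	TNFRSF1A
TRADD	apoptosis_pathway
FADD	apoptosis_pathway
DAXX	apoptosis_pathway
CASP8	apoptosis_pathway
CASP10	apoptosis_pathway
CASP9	apoptosis_pathway
CASP12	apoptosis_pathway
CASP3	apoptosis_pathway
CASP6	apoptosis_pathway
CASP7	apoptosis_pathway
BAX	apoptosis_pathway
BAK	apoptosis_pathway	BAK1
BID	apoptosis_pathway
BCL2	apoptosis_pathway
BCL2L1	apoptosis_pathway	BCLXL
DIABLO	apoptosis_pathway	SMAC
CYCS	apoptosis_pathway
APAF1	apoptosis_pathway
TP53	apoptosis_pathway
CAPN1	apoptosis_pathway
CAPN2	apoptosis_pathway
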