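# Illustrative TCGA GBM subtype marker sets (synthetic stand-in).
# These are widely used subtype markers assembled for demonstration only;
# they are NOT the published classifier gene lists. Supply your own TSV
# (columns: signature, gene) for real analyses. Tests never rely on this file.
signature	gene
PN	OLIG2
PN	DLL3
PN	SOX2
PN	DCX
PN	CD24
PN	PDGFRA
PN	NKX2-2
PN	ERBB3
CL	EGFR
CL	NES
CL	AKT2
CL	NOTCH3
CL	JAG1
CL	SMO
CL	GLI2
CL	CDKN2A
MES	CD44
MES	CHI3L1
MES	RELB
MES	TRADD
MES	CASP1
MES	CASP4
MES	TLR2
MES	TLR4
NL	NEFL
NL	GABRA1
NL	SYT1
NL	SLC12A5
NL	SNAP91
NL	GRIA2
cilium	HYDIN
cilium	FOXJ1
cilium	DNALI1
cilium	FAM183A
cilium	SPAG6
cilium	TEKT1
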