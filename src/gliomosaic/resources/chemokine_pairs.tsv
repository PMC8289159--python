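# Chemokine ligand-receptor pair panel (curated from standard chemokine
# receptor pharmacology; family column groups pairs by receptor family).
ligand	receptor	family
CX3CL1	CX3CR1	CX3C
CXCL16	CXCR6	CXC
CXCL9	CXCR3	CXC
CXCL10	CXCR3	CXC
CXCL11	CXCR3	CXC
CXCL12	CXCR4	CXC
CXCL1	CXCR1	CXC
CXCL1	CXCR2	CXC
CXCL2	CXCR1	CXC
CXCL2	CXCR2	CXC
CXCL3	CXCR1	CXC
CXCL3	CXCR2	CXC
CXCL5	CXCR1	CXC
CXCL5	CXCR2	CXC
CXCL6	CXCR1	CXC
CXCL6	CXCR2	CXC
CXCL8	CXCR1	CXC
CXCL8	CXCR2	CXC
CCL5	CCR5	CC
CCL8	CCR5	CC
CCL8	CCR2	CC
CCL20	CCR6	CC
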