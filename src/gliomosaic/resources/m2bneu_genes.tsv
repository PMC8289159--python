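# Placeholder M2b-macrophage/neutrophil burden panel (synthetic stand-in).
# Assembled from genes central to M2b polarization and neutrophil biology;
# NOT the published 38-gene enrichment list (supplementary-only). Supply your
# own list for real analyses; tests use synthetic sets.
CXCL1
CXCL2
CXCL3
CXCL5
CXCL6
CXCL8
CXCR1
CXCR2
IL1RN
VEGFA
ITGA4
CD163
IL1B
IL6
IL10
TNF
CCL3
CCL4
CCL20
S100A8
S100A9
S100A11
FCGR3B
FCGR2A
CSF3R
FPR1
TREM1
MMP9
PLAUR
SERPINB2
SOCS3
OSM
ITGAM
CD86
SELL
ICAM1
TIMP1
THBS1
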