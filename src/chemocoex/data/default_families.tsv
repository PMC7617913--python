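family	receptor	ligands
CXCR3	CXCR3	CXCL9,CXCL10,CXCL11
CXCR1_CXCR2	CXCR1,CXCR2	CXCL1,CXCL2,CXCL3,CXCL5,CXCL6,PPBP,CXCL8
CXCR5	CXCR5	CXCL13
CXCR6	CXCR6	CXCL16
CCR1	CCR1	CCL3,CCL5,CCL7,CCL14,CCL15,CCL23
CCR4	CCR4	CCL17,CCL22
CCR6	CCR6	CCL20
CCR7	CCR7	CCL19,CCL21
CCR8	CCR8	CCL1,CCL18
CCR10	CCR10	CCL27,CCL28
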