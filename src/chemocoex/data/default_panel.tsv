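symbol	category	mouse_symbol
CXCL1	chemokine_ligand	Cxcl1
CXCL2	chemokine_ligand	Cxcl2
CXCL3	chemokine_ligand	Cxcl3
PF4	chemokine_ligand	Pf4
PF4V1	chemokine_ligand
CXCL5	chemokine_ligand	Cxcl5
CXCL6	chemokine_ligand
PPBP	chemokine_ligand	Ppbp
CXCL8	chemokine_ligand
CXCL9	chemokine_ligand	Cxcl9
CXCL10	chemokine_ligand	Cxcl10
CXCL11	chemokine_ligand	Cxcl11
CXCL12	chemokine_ligand	Cxcl12
CXCL13	chemokine_ligand	Cxcl13
CXCL14	chemokine_ligand	Cxcl14
CXCL16	chemokine_ligand	Cxcl16
CXCL17	chemokine_ligand	Cxcl17
CCL1	chemokine_ligand	Ccl1
CCL2	chemokine_ligand	Ccl2
CCL3	chemokine_ligand	Ccl3
CCL4	chemokine_ligand	Ccl4
CCL5	chemokine_ligand	Ccl5
CCL7	chemokine_ligand	Ccl7
CCL8	chemokine_ligand	Ccl8
CCL11	chemokine_ligand	Ccl11
CCL13	chemokine_ligand
CCL14	chemokine_ligand
CCL15	chemokine_ligand
CCL16	chemokine_ligand
CCL17	chemokine_ligand	Ccl17
CCL18	chemokine_ligand
CCL19	chemokine_ligand	Ccl19
CCL20	chemokine_ligand	Ccl20
CCL21	chemokine_ligand	Ccl21a
CCL22	chemokine_ligand	Ccl22
CCL23	chemokine_ligand
CCL24	chemokine_ligand	Ccl24
CCL25	chemokine_ligand	Ccl25
CCL26	chemokine_ligand	Ccl26
CCL27	chemokine_ligand	Ccl27a
CCL28	chemokine_ligand	Ccl28
XCL1	chemokine_ligand	Xcl1
XCL2	chemokine_ligand
CX3CL1	chemokine_ligand	Cx3cl1
CXCR1	chemokine_receptor	Cxcr1
CXCR2	chemokine_receptor	Cxcr2
CXCR3	chemokine_receptor	Cxcr3
CXCR4	chemokine_receptor	Cxcr4
CXCR5	chemokine_receptor	Cxcr5
CXCR6	chemokine_receptor	Cxcr6
CCR1	chemokine_receptor	Ccr1
CCR2	chemokine_receptor	Ccr2
CCR3	chemokine_receptor	Ccr3
CCR4	chemokine_receptor	Ccr4
CCR5	chemokine_receptor	Ccr5
CCR6	chemokine_receptor	Ccr6
CCR7	chemokine_receptor	Ccr7
CCR8	chemokine_receptor	Ccr8
CCR9	chemokine_receptor	Ccr9
CCR10	chemokine_receptor	Ccr10
XCR1	chemokine_receptor	Xcr1
CX3CR1	chemokine_receptor	Cx3cr1
ACKR1	chemokine_receptor	Ackr1
ACKR2	chemokine_receptor	Ackr2
ACKR3	chemokine_receptor	Ackr3
ACKR4	chemokine_receptor	Ackr4
CCRL2	chemokine_receptor	Ccrl2
EXT1	gag_synthesis	Ext1
EXT2	gag_synthesis	Ext2
EXTL1	gag_synthesis	Extl1
EXTL2	gag_synthesis	Extl2
EXTL3	gag_synthesis	Extl3
NDST1	gag_synthesis	Ndst1
NDST2	gag_synthesis	Ndst2
NDST3	gag_synthesis	Ndst3
NDST4	gag_synthesis	Ndst4
GLCE	gag_synthesis	Glce
HS2ST1	gag_synthesis	Hs2st1
HS6ST1	gag_synthesis	Hs6st1
HS6ST2	gag_synthesis	Hs6st2
HS6ST3	gag_synthesis	Hs6st3
HS3ST1	gag_synthesis	Hs3st1
HS3ST2	gag_synthesis	Hs3st2
HS3ST3A1	gag_synthesis	Hs3st3a1
MMP1	mmp
MMP2	mmp	Mmp2
MMP3	mmp	Mmp3
MMP7	mmp	Mmp7
MMP8	mmp	Mmp8
MMP9	mmp	Mmp9
MMP10	mmp	Mmp10
MMP11	mmp	Mmp11
MMP12	mmp	Mmp12
MMP13	mmp	Mmp13
MMP14	mmp	Mmp14
MMP15	mmp	Mmp15
MMP16	mmp	Mmp16
MMP17	mmp	Mmp17
MMP19	mmp	Mmp19
MMP20	mmp	Mmp20
MMP21	mmp	Mmp21
MMP23A	mmp
MMP23B	mmp	Mmp23
MMP24	mmp	Mmp24
MMP25	mmp	Mmp25
MMP26	mmp
MMP27	mmp	Mmp27
MMP28	mmp	Mmp28
XYLT1	proteoglycan_synthesis	Xylt1
XYLT2	proteoglycan_synthesis	Xylt2
B4GALT7	proteoglycan_synthesis	B4galt7
B3GALT6	proteoglycan_synthesis	B3galt6
B3GAT3	proteoglycan_synthesis	B3gat3
CSGALNACT1	proteoglycan_synthesis	Csgalnact1
CSGALNACT2	proteoglycan_synthesis	Csgalnact2
CHSY1	proteoglycan_synthesis	Chsy1
CHSY3	proteoglycan_synthesis	Chsy3
CHPF	proteoglycan_synthesis	Chpf
CHPF2	proteoglycan_synthesis	Chpf2
SDC1	proteoglycan_synthesis	Sdc1
SDC2	proteoglycan_synthesis	Sdc2
SDC3	proteoglycan_synthesis	Sdc3
SDC4	proteoglycan_synthesis	Sdc4
GPC1	proteoglycan_synthesis	Gpc1
GPC2	proteoglycan_synthesis	Gpc2
GPC3	proteoglycan_synthesis	Gpc3
GPC4	proteoglycan_synthesis	Gpc4
GPC5	proteoglycan_synthesis	Gpc5
GPC6	proteoglycan_synthesis	Gpc6
SRGN	proteoglycan_synthesis	Srgn
HSPG2	proteoglycan_synthesis	Hspg2
AGRN	proteoglycan_synthesis	Agrn
VCAN	proteoglycan_synthesis	Vcan
DCN	proteoglycan_synthesis	Dcn
BGN	proteoglycan_synthesis	Bgn
LUM	proteoglycan_synthesis	Lum
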