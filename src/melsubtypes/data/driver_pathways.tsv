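pathway	process	genes
NOTCH	cell_fate	FBXW7,NOTCH1,NOTCH2
HH	cell_fate	PTCH1,SMO
APC	cell_fate	APC,AXIN1,CDH1,CTNNB1,FAM123B,HNF1A,NF2
Chromatin modification	cell_fate	ARID1A,ARID1B,ATRX,DNMT1,DNMT3A,EXH2,KDM6A,MEN1,MLL2,MLL3,PBRM1,SETD2,SMARCA4,SMARCB1
Transcriptional regulation	cell_fate	AR,GATA3,RUNX1
DNA damage control	genome_maintenance	ATM,BAP1,BRCA1,BRCA2,MLH1,MSH2,MSH6
TGF-beta	cell_survival	ACVR1B,SMAD4
MAPK	cell_survival	GNA11,GNAQ
STAT	cell_survival	JAK1,JAK2,JAK3
PI3K	cell_survival	AKT1,PIK3CA,PIK3R1,PTEN,TSC1
RAS	cell_survival	BRAF,CIC,HRAS,KRAS,NF1,NRAS,PTPN11
Cell cycle/Apoptosis	cell_survival	ABL1,BCL2,CASP8,CDC73,CDKN2A,CYLD,RB1,TRAF7
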