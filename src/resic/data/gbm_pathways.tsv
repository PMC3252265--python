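# Curator-reviewed GBM signaling-pathway definitions (TCGA/Pathway Commons
# style).  effect: + means the gene increases production of the pathway's
# signaling product when amplified (deletion has the reverse effect);
# - means amplification decreases it.  oncogenic_direction: the signaling
# change treated as tumor-promoting for the collapsed event.
pathway	gene	effect	oncogenic_direction
TP53	TP53	+	inactivation
TP53	CDKN2A	+	inactivation
TP53	MDM2	-	inactivation
TP53	MDM4	-	inactivation
PIK3C1/AKT	AKT1	+	activation
PIK3C1/AKT	AKT2	+	activation
PIK3C1/AKT	AKT3	+	activation
PIK3C1/AKT	GAB1	+	activation
PIK3C1/AKT	IRS1	+	activation
PIK3C1/AKT	PIK3CA	+	activation
PIK3C1/AKT	PIK3CB	+	activation
PIK3C1/AKT	PIK3CD	+	activation
PIK3C1/AKT	PIK3CG	+	activation
PIK3C1/AKT	PIK3R1	+	activation
PIK3C1/AKT	PIK3R2	+	activation
PIK3C1/AKT	PDPK1	+	activation
PIK3C1/AKT	SRC	+	activation
PIK3C1/AKT	PTEN	-	activation
PIK3C2	PIK3C2A	+	activation
PIK3C2	PIK3C2B	+	activation
PIK3C2	PIK3C2G	+	activation
RAS	ARAF	+	activation
RAS	BRAF	+	activation
RAS	HRAS	+	activation
RAS	KRAS	+	activation
RAS	NRAS	+	activation
RAS	EGFR	+	activation
RAS	ERBB2	+	activation
RAS	ERBB3	+	activation
RAS	FGFR1	+	activation
RAS	FGFR2	+	activation
RAS	GRB2	+	activation
RAS	IGFR	+	activation
RAS	MET	+	activation
RAS	PDGFRA	+	activation
RAS	PDGFRB	+	activation
RAS	RAF1	+	activation
RAS	CBL	-	activation
RAS	ERRFI1	-	activation
RAS	SPRY2	-	activation
RB	CDKN1A	+	inactivation
RB	CDKN1B	+	inactivation
RB	CDKN2A	+	inactivation
RB	CDKN2B	+	inactivation
RB	CDKN2C	+	inactivation
RB	RB1	+	inactivation
RB	CCND1	-	inactivation
RB	CCND2	-	inactivation
RB	CCNE1	-	inactivation
RB	CDK2	-	inactivation
RB	CDK4	-	inactivation
RB	CDK6	-	inactivation
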