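gene_id	chrom	start	end	strand	symbol
ENSG00000183779	chr8	37553329	37557582	+	ZNF703
ENSG00000077782	chr8	38268656	38326352	-	FGFR1
ENSG00000136997	chr8	128748315	128753680	+	MYC
ENSG00000105173	chr19	30302805	30315215	+	CCNE1
ENSG00000141736	chr17	37844393	37884915	+	ERBB2
ENSG00000121879	chr3	178866311	178952497	+	PIK3CA
ENSG00000141510	chr17	7571720	7590868	-	TP53
ENSG00000171862	chr10	89623195	89728532	+	PTEN
ENSG00000139687	chr13	48877887	49056122	+	RB1
ENSG00000107485	chr10	8096667	8117164	+	GATA3
ENSG00000091831	chr6	152011631	152424408	+	ESR1
ENSG00000039068	chr16	68771195	68869444	+	CDH1
ENSG00000147889	chr9	21967751	21995300	-	CDKN2A
ENSG00000012048	chr17	41196312	41277500	-	BRCA1
ENSG00000139618	chr13	32889617	32973809	+	BRCA2
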