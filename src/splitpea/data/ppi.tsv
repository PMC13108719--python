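# synthetic toy reference data (generated by splitpea.fixtures; not real biology)
gene_a	gene_b	source
GENE1	GENE8	toy
GENE1	GENE9	toy
GENE1	GENE10	toy
GENE2	GENE3	toy
GENE2	GENE5	toy
GENE2	GENE9	toy
GENE2	GENE12	toy
GENE3	GENE4	toy
GENE3	GENE8	toy
GENE4	GENE5	toy
GENE4	GENE6	toy
GENE4	GENE9	toy
GENE4	GENE10	toy
GENE4	GENE12	toy
GENE6	GENE7	toy
GENE6	GENE9	toy
GENE6	GENE11	toy
GENE6	GENE12	toy
GENE7	GENE8	toy
GENE7	GENE10	toy
GENE8	GENE9	toy
GENE8	GENE11	toy
GENE9	GENE12	toy
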