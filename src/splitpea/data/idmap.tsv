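# synthetic toy reference data (generated by splitpea.fixtures; not real biology)
raw_id	gene_id
GENE1	1001
ENSG00000000001	1001
1001	1001
GENE2	1002
ENSG00000000002	1002
1002	1002
GENE3	1003
ENSG00000000003	1003
1003	1003
GENE4	1004
ENSG00000000004	1004
1004	1004
GENE5	1005
ENSG00000000005	1005
1005	1005
GENE6	1006
ENSG00000000006	1006
1006	1006
GENE7	1007
ENSG00000000007	1007
1007	1007
GENE8	1008
ENSG00000000008	1008
1008	1008
GENE9	1009
ENSG00000000009	1009
1009	1009
GENE10	1010
ENSG00000000010	1010
1010	1010
GENE11	1011
ENSG00000000011	1011
1011	1011
GENE12	1012
ENSG00000000012	1012
1012	1012
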