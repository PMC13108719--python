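# synthetic toy reference data (generated by splitpea.fixtures; not real biology)
gene_id	pfam_id	chrom	strand	intervals
GENE1	PF00006	chr1	-	2255-2595
GENE1	PF00004	chr1	-	2701-2883
GENE1	PF00005	chr1	-	2948-3398,3654-3900
GENE2	PF00002	chr2	+	2225-2499,2565-3054
GENE2	PF00004	chr2	+	3273-3695,3934-4152
GENE3	PF00004	chr3	-	2060-2401
GENE3	PF00002	chr3	-	2621-3093,3329-3607
GENE4	PF00004	chr4	-	2276-2555
GENE4	PF00001	chr4	-	2803-3019
GENE4	PF00004	chr4	-	3240-3556
GENE5	PF00002	chr5	+	2217-2696,2855-3061
GENE6	PF00006	chr6	-	2074-2333,2574-3015
GENE6	PF00004	chr6	-	3275-3560,3834-4084
GENE6	PF00002	chr6	-	4293-4491,4749-4968
GENE7	PF00001	chr7	-	2246-2669,2885-3200
GENE7	PF00006	chr7	-	3445-3789
GENE7	PF00004	chr7	-	3981-4144,4228-4463
GENE8	PF00004	chr8	-	2213-2527,2790-3137
GENE9	PF00007	chr9	+	2208-2555,2743-2924
GENE10	PF00007	chr10	+	2200-2360
GENE10	PF00003	chr10	+	2655-2880
GENE11	PF00004	chr11	+	2263-2425,2533-2970
GENE12	PF00007	chr12	-	2279-2531
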