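# ascn-assoc packaged table: published glioma risk variants (discovery-array surrogates)
variant_id	chrom	pos	gene	major_allele	risk_allele	surrogate_id	surrogate_pos	surrogate_r2
rs2736100	5	1339516	TERT	A	C	NA	NA	NA
rs2252586	7	54946418	EGFR	G	A	rs6945082	54925952	0.883
rs6969537	7	55049912	EGFR	G	G	NA	NA	NA
rs17172430	7	55090144	EGFR	G	G	rs1015793	55081810	0.742
rs11979158	7	55126843	EGFR	A	A	rs10245472	55114972	1.000
rs4947979	7	55163119	EGFR	A	A	NA	NA	NA
rs4295627	8	130754639	CCDC26	A	C	rs6470745	130711103	1.000
rs1412829	9	22033926	CDKN2B	A	G	rs634537	22022152	1.000
rs4977756	9	22058652	CDKN2A-CDKN2B	A	G	NA	NA	NA
rs498872	11	117982577	PHLDB1	G	A	NA	NA	NA
rs1476278	17	35089769	ERBB2	A	G	rs903502	35083130	1.000
rs2952155	17	35115244	ERBB2	G	A	rs9635726	35273667	0.678
rs6010620	20	61780283	RTEL1	G	G	NA	NA	NA
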