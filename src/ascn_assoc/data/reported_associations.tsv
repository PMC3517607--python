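# ascn-assoc packaged table: published 2x2 counts, risk group vs other group, per cohort
assoc_id	cohort	variant_id	marker_used	region	gene	event	approach	n_risk	n_risk_event	n_other	n_other_event
egfr_loh	discovery	rs17172430	rs1015793	chr7:55054218-55242525	EGFR	LOH	GOI	60	19	21	2
egfr_loh	validation	rs17172430	rs17172430	chr7:55054218-55242525	EGFR	LOH	GOI	236	57	49	6
cdkn2a_hd	discovery	rs11979158	rs10245472	chr9:21957750-21965132	CDKN2A	HD	GOI	57	33	24	8
cdkn2a_hd	validation	rs11979158	rs11979158	chr9:21957750-21965132	CDKN2A	HD	GOI	209	51	76	10
cdkn2b_hd_rs11979158	discovery	rs11979158	rs10245472	chr9:21992901-21999312	CDKN2B	HD	GOI	57	32	24	7
cdkn2b_hd_rs11979158	validation	rs11979158	rs11979158	chr9:21992901-21999312	CDKN2B	HD	GOI	209	122	76	32
cdkn2b_hd_rs17172430	discovery	rs17172430	rs1015793	chr9:21992901-21999312	CDKN2B	HD	GOI	60	34	21	5
cdkn2b_hd_rs17172430	validation	rs17172430	rs17172430	chr9:21992901-21999312	CDKN2B	HD	GOI	236	134	49	20
mtap_cdkn2a_hd	discovery	rs17172430	rs1015793	chr9:21961989-21978896	MTAP-CDKN2A	HD	global	60	35	21	5
mtap_cdkn2a_hd	validation	rs17172430	rs17172430	chr9:21961989-21978896	MTAP-CDKN2A	HD	global	236	135	49	20
mtap_cdkn2bas_hd	discovery	rs17172430	rs1015793	chr9:22010493-22055620	MTAP-CDKN2BAS	HD	global	60	33	21	4
mtap_cdkn2bas_hd	validation	rs17172430	rs17172430	chr9:22010493-22055620	MTAP-CDKN2BAS	HD	global	236	132	49	19
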