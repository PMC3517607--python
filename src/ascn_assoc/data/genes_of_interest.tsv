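# ascn-assoc packaged table: glioma genes of interest coords=one-based
name	chrom	start	end
CDKN2C	1	51206954	51212894
MDM4	1	202752129	202793871
AKT3	1	241729643	242073207
IDH1	2	208809197	208828051
PIK3CA	3	180349004	180435191
PDGFRA	4	54790020	54859169
TERT	5	1306286	1348162
PIK3R1	5	67547339	67633405
PARK2	6	161688579	163068824
EGFR	7	55054218	55242525
CDK6	7	92072170	92301167
MET	7	116099694	116225676
MYC	8	128817496	128822862
CCDC26	8	130433119	130761667
CDKN2A	9	21957750	21965132
CDKN2B	9	21992901	21999312
PTEN	10	89613174	89718512
PHLDB1	11	117982422	118033958
CCND2	12	4253162	4284783
CDK4	12	56427776	56432497
MDM2	12	67488237	67525479
RB1	13	47775883	47954027
IDH2	15	88428215	88446712
TP53	17	7512444	7531593
NF1	17	26446070	26728821
ERBB2	17	35109779	35138441
RTEL1	20	61759606	61798050
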