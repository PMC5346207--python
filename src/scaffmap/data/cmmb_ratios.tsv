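map_id	chromosome	ratio	coverage_fraction
TxE	1	1.642	0.986
TxE	2	1.433	0.980
TxE	3	1.623	0.993
TxE	4	2.070	0.966
TxE	5	2.751	0.935
TxE	6	2.666	0.988
TxE	7	3.360	0.938
TxE	8	2.590	0.983
PxF	1	2.506	0.979
PxF	2	2.365	0.986
PxF	3	2.672	0.956
PxF	4	2.754	0.974
PxF	5	3.452	0.973
PxF	6	2.705	0.975
PxF	7	3.031	0.992
PxF	8	3.310	0.905
PxF_F1	1	2.984	0.979
PxF_F1	2	2.971	0.975
PxF_F1	3	2.748	0.956
PxF_F1	4	3.048	0.974
PxF_F1	5	3.285	0.973
PxF_F1	6	3.115	0.949
PxF_F1	7	3.130	0.908
PxF_F1	8	3.405	0.890
PxF_recurrent	1	1.354	0.829
PxF_recurrent	2	1.402	0.727
PxF_recurrent	3	NA	NA
PxF_recurrent	4	2.317	0.738
PxF_recurrent	5	4.855	0.307
PxF_recurrent	6	1.708	0.873
PxF_recurrent	7	5.928	0.148
PxF_recurrent	8	3.431	0.134
CxA	1	2.133	0.960
CxA	2	1.847	0.646
CxA	3	2.485	0.996
CxA	4	2.575	0.969
CxA	5	4.967	0.397
CxA	6	2.677	0.970
CxA	7	2.884	0.965
CxA	8	2.918	0.978
WxB	1	2.261	0.93
WxB	2	2.141	0.93
WxB	3	2.340	0.93
WxB	4	2.544	0.93
WxB	5	3.777	0.93
WxB	6	2.393	0.93
WxB	7	3.003	0.93
WxB	8	2.775	0.93
DvsS	1	1.858	0.95
DvsS	2	1.435	0.95
DvsS	3	2.174	0.95
DvsS	4	2.384	0.95
DvsS	5	2.672	0.95
DvsS	6	1.770	0.95
DvsS	7	1.930	0.95
DvsS	8	1.812	0.95
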