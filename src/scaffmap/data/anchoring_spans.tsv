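map_id	chromosome	cM_span	bp_span
TxE	1	77.5	47190243
TxE	2	42.7	29794491
TxE	3	44.1	27174422
TxE	4	51.7	24974520
TxE	5	47.6	17300580
TxE	6	81	30384999
TxE	7	70.6	21009142
TxE	8	57.5	22199033
PxF	1	117.4	46854330
PxF	2	70.9	29975524
PxF	3	69.9	26162111
PxF	4	69.3	25167755
PxF	5	62.1	17989526
PxF	6	81.1	29985579
PxF	7	67.3	22201468
PxF	8	67.6	20421932
PxF_F1	1	139.8	46854330
PxF_F1	2	88.1	29652167
PxF_F1	3	71.9	26162111
PxF_F1	4	76.7	25167755
PxF_F1	5	59.1	17989526
PxF_F1	6	91	29209364
PxF_F1	7	63.6	20322548
PxF_F1	8	68.4	20087434
PxF_recurrent	1	53.7	39665700
PxF_recurrent	2	31	22115897
PxF_recurrent	3	NA	NA
PxF_recurrent	4	44.2	19074112
PxF_recurrent	5	27.6	5684854
PxF_recurrent	6	45.9	26868520
PxF_recurrent	7	19.6	3306229
PxF_recurrent	8	10.4	3031158
CxA	1	98	45955086
CxA	2	36.3	19656032
CxA	3	67.7	27246203
CxA	4	64.5	25053083
CxA	5	36.5	7348324
CxA	6	79.9	29848481
CxA	7	62.3	21600273
CxA	8	64.4	22073557
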