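chromosome	length_bp
1	47851208
2	30405870
3	27368013
4	25843236
5	18496696
6	30767194
7	22388614
8	22573980
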