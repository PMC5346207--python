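chromosome	contigs_used	gaps_closed	gap_bases_patched	initial_contig_bp	post_patch_contig_bp	bases_gained	indels_corrected	snps_corrected
1	36	36	6820	47412656	47417444	4788	269	143
2	27	27	6884	29982897	29985295	2398	185	117
3	29	30	4831	27022361	27022947	586	167	128
4	24	24	3895	25545546	25549276	3730	133	132
5	19	21	10824	18291031	18295669	4638	110	58
6	25	26	9635	30419305	30423361	4056	197	117
7	29	30	7501	22049797	22053146	3349	157	75
8	17	18	3485	22391144	22392798	1654	129	89
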