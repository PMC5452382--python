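chr1	1930	2114
chr1	2664	2968
chr1	2936	3450
chr1	3367	3658
chr1	3763	4072
chr1	8575	8870
chr1	8710	9077
chr1	13866	14024
chr1	13901	14168
chr1	14400	14709
chr1	16836	17189
chr1	17390	17703
chr1	17693	17846
chr1	18512	18832
chr1	19805	20007
chr1	21287	21519
chr1	22068	22274
chr1	23978	24237
chr1	25083	25329
chr1	27473	27656
chr1	29475	29664
chr1	31722	32114
chr1	32069	32255
chr1	32528	32860
chr1	32692	32914
chr1	32960	33312
chr1	33258	33611
chr1	35602	35951
chr1	37150	37381
chr1	38882	39124
chr1	39031	39214
chr1	40648	40977
chr1	40925	41086
chr1	41594	41905
chr1	42074	42271
chr1	42227	42558
chr1	43019	43287
chr1	43208	43523
chr1	44391	44762
chr1	46777	47060
chr1	46893	47175
chr1	47442	47692
chr1	47877	48411
chr1	48163	48492
chr1	49172	49842
chr2	1767	1951
chr2	4465	4670
chr2	4968	5347
chr2	6599	6972
chr2	8752	9031
chr2	9262	9538
chr2	9752	9903
chr2	10335	10583
chr2	12268	12553
chr2	15133	15383
chr2	18004	18223
chr2	19310	19492
chr2	19697	20087
chr2	21367	21572
chr2	22779	23117
chr2	24366	24754
chr2	26434	26828
chr2	29846	30135
chr2	30077	30394
chr2	30390	30648
chr2	31854	32046
chr2	34858	35239
chr2	34994	35233
chr2	37340	37639
chr2	37836	38130
chr2	39486	39835
chr2	40280	40633
chr2	40810	41174
chr2	42058	42328
chr2	44331	44512
chr2	44955	45265
chr2	46662	47055
chr2	46985	47359
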