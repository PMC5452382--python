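chr1	1257	1655
chr1	2374	2558
chr1	2712	3226
chr1	4953	5211
chr1	5270	5599
chr1	5739	5991
chr1	6663	6870
chr1	8470	8678
chr1	8538	9068
chr1	9706	10024
chr1	17282	17642
chr1	17631	17781
chr1	20402	20557
chr1	20481	20870
chr1	20959	21337
chr1	21607	21783
chr1	21790	22185
chr1	22126	22441
chr1	22843	23049
chr1	26789	27107
chr1	27875	28140
chr1	28245	28514
chr1	28836	29226
chr1	32344	32511
chr1	33278	33628
chr1	35140	35331
chr1	36165	36910
chr1	39616	39829
chr1	43675	43927
chr1	44635	44791
chr1	44963	45262
chr1	47026	47252
chr1	48688	49069
chr1	49055	49285
chr1	49552	49831
chr1	49578	49838
chr2	2352	2592
chr2	3487	3776
chr2	5337	5622
chr2	7969	8290
chr2	8675	8906
chr2	8703	8979
chr2	8722	8878
chr2	10414	10752
chr2	11334	11628
chr2	13514	13859
chr2	16426	16680
chr2	21589	21871
chr2	24891	25222
chr2	25057	25232
chr2	25133	25311
chr2	29709	30018
chr2	30502	30853
chr2	31529	31921
chr2	32616	32789
chr2	33443	33728
chr2	35584	35969
chr2	35746	36055
chr2	37306	37565
chr2	37886	38096
chr2	39904	40101
chr2	40493	40846
chr2	41280	41530
chr2	42391	42686
chr2	43841	44162
chr2	43888	44213
chr2	43929	44275
chr2	44537	44688
chr2	45627	45937
chr2	45886	46236
chr2	46072	46367
chr2	46429	46728
chr2	48242	48570
chr2	48293	48640
chr2	49072	49251
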