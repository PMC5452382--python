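chr1	2291	2475
chr1	2812	3326
chr1	4374	4670
chr1	5660	5957
chr1	6507	6687
chr1	8922	9217
chr1	10064	10382
chr1	10649	10896
chr1	13339	13578
chr1	13581	13739
chr1	16064	16336
chr1	17123	17436
chr1	18831	19515
chr1	19032	19372
chr1	20631	20929
chr1	21917	22306
chr1	22047	22256
chr1	23875	24087
chr1	24576	24849
chr1	25499	25873
chr1	26860	27127
chr1	27517	27700
chr1	27826	28113
chr1	27836	28412
chr1	28023	28378
chr1	28494	28790
chr1	32530	32862
chr1	32966	33318
chr1	35372	35563
chr1	35765	36061
chr1	36011	36360
chr1	39192	39588
chr1	39232	39402
chr1	39358	39712
chr1	40012	40399
chr1	41190	41714
chr1	41248	41503
chr1	41835	42161
chr1	42331	42811
chr1	43298	43552
chr1	43747	44058
chr1	45749	45961
chr1	46794	47070
chr1	48263	48490
chr1	48965	49635
chr1	49235	49438
chr2	331	672
chr2	570	1086
chr2	4859	5078
chr2	5415	5780
chr2	9320	9596
chr2	10735	11067
chr2	12760	13117
chr2	13175	13520
chr2	16476	16736
chr2	16548	16700
chr2	17177	17552
chr2	18894	19064
chr2	19539	19721
chr2	20179	20569
chr2	22118	22463
chr2	23805	24127
chr2	24928	25106
chr2	25132	25531
chr2	28683	28833
chr2	29924	30267
chr2	30557	30915
chr2	33026	33410
chr2	33219	33504
chr2	36279	36480
chr2	37271	37570
chr2	37806	38319
chr2	37841	38162
chr2	38202	38358
chr2	38522	38778
chr2	38914	39152
chr2	39050	39442
chr2	39666	40015
chr2	41058	41308
chr2	41853	42233
chr2	41868	42068
chr2	42660	42836
chr2	45708	46064
chr2	46391	46686
chr2	46732	47017
chr2	48335	48682
chr2	48631	48968
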