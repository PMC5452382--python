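chr1	1091	1452
chr1	1603	1922
chr1	2266	2450
chr1	2885	3272
chr1	3148	3399
chr1	3547	3838
chr1	4438	4815
chr1	5218	5522
chr1	5620	5917
chr1	5982	6345
chr1	6216	6429
chr1	7719	8028
chr1	8098	8386
chr1	8373	8628
chr1	8893	9048
chr1	9012	9188
chr1	10054	10313
chr1	10059	10372
chr1	10553	10948
chr1	10575	10843
chr1	11800	12165
chr1	13277	13516
chr1	13553	13711
chr1	17112	17425
chr1	17859	18203
chr1	17885	18038
chr1	18880	19121
chr1	19094	19338
chr1	19167	19553
chr1	19331	19564
chr1	21281	21513
chr1	21775	22164
chr1	22402	22608
chr1	25536	25910
chr1	26795	27062
chr1	27382	27565
chr1	27716	28082
chr1	27744	27908
chr1	27800	27980
chr1	27993	28292
chr1	28404	28700
chr1	29721	29956
chr1	32524	32856
chr1	33090	33442
chr1	35242	35433
chr1	35902	36251
chr1	36380	36752
chr1	36734	37090
chr1	36900	37125
chr1	37868	38049
chr1	39287	39683
chr1	39319	39616
chr1	40854	41077
chr1	41203	41358
chr1	41339	41727
chr1	41893	42219
chr1	42241	42608
chr1	42470	42721
chr1	42823	43209
chr1	42893	43235
chr1	42927	43186
chr1	43841	44152
chr1	45655	45867
chr1	46941	47224
chr1	47609	47966
chr1	47815	48143
chr1	48888	49228
chr1	48892	49247
chr1	49204	49558
chr1	49486	49776
chr2	624	789
chr2	722	997
chr2	785	1140
chr2	4928	5102
chr2	5017	5278
chr2	5367	5732
chr2	5426	5686
chr2	6488	6844
chr2	9181	9457
chr2	12618	12975
chr2	12673	12922
chr2	13107	13452
chr2	16427	16687
chr2	17395	17589
chr2	19001	19171
chr2	19474	19777
chr2	19641	19823
chr2	20066	20358
chr2	20134	20512
chr2	20218	20456
chr2	23707	24029
chr2	25024	25202
chr2	33270	33555
chr2	36230	36431
chr2	37239	37538
chr2	37678	37906
chr2	37838	38191
chr2	39019	39257
chr2	39742	40091
chr2	40163	40516
chr2	40971	41221
chr2	45652	46008
chr2	46273	46568
chr2	46957	47350
chr2	48292	48639
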