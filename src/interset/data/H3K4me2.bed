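chr1	1136	1440
chr1	1373	1612
chr1	2254	2409
chr1	2344	2517
chr1	2353	2537
chr1	3076	3250
chr1	3674	3965
chr1	5089	5396
chr1	5698	5995
chr1	6095	6308
chr1	7934	8464
chr1	9020	9315
chr1	9499	9739
chr1	9984	10336
chr1	11452	11760
chr1	16125	16329
chr1	16235	16503
chr1	17122	17519
chr1	17536	17782
chr1	17603	17767
chr1	17963	18116
chr1	18015	18303
chr1	18633	18889
chr1	19015	19699
chr1	20926	21164
chr1	25551	25925
chr1	27816	28392
chr1	28551	28847
chr1	28560	28829
chr1	32502	32834
chr1	32916	33268
chr1	34605	34796
chr1	39825	40099
chr1	40257	40514
chr1	40370	40696
chr1	40651	40922
chr1	40845	41095
chr1	42284	42451
chr1	42704	43116
chr1	43560	43751
chr1	43687	43998
chr1	44250	44482
chr1	44573	44875
chr1	45702	45914
chr1	47047	47330
chr1	47778	48312
chr1	47972	48361
chr1	48393	48645
chr1	48724	49394
chr1	49187	49359
chr2	1126	1461
chr2	3332	3541
chr2	5061	5411
chr2	5674	5895
chr2	9096	9372
chr2	10981	11257
chr2	17425	17734
chr2	18888	19058
chr2	19661	19843
chr2	22505	22706
chr2	22660	22841
chr2	29565	29823
chr2	29850	30093
chr2	34132	34493
chr2	35532	35779
chr2	35702	36030
chr2	40002	40355
chr2	40805	41055
chr2	42212	42413
chr2	48644	48969
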