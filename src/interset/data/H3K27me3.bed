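chr1	1090	1385
chr1	2541	2725
chr1	2568	2792
chr1	3144	3658
chr1	5785	6082
chr1	6556	6752
chr1	8096	8626
chr1	8563	8860
chr1	8750	8937
chr1	10068	10386
chr1	11878	12127
chr1	12619	12973
chr1	13011	13176
chr1	14115	14292
chr1	17821	17983
chr1	17986	18139
chr1	19300	19459
chr1	19551	19840
chr1	20204	20371
chr1	22395	22601
chr1	23250	23639
chr1	23926	24278
chr1	24474	24724
chr1	27009	27276
chr1	30042	30240
chr1	33322	33674
chr1	34422	34758
chr1	35260	35583
chr1	35520	35801
chr1	36645	37390
chr1	37408	37785
chr1	39514	39802
chr1	40836	41149
chr1	41801	42127
chr1	41940	42203
chr1	42688	42908
chr1	43054	43338
chr1	43799	44110
chr1	44364	44733
chr1	45445	45657
chr1	45695	46015
chr1	46874	47157
chr1	47033	47194
chr1	48759	49429
chr2	496	1012
chr2	998	1296
chr2	2899	3190
chr2	3337	3493
chr2	4831	5181
chr2	6589	6945
chr2	9825	9977
chr2	11577	11917
chr2	12649	12910
chr2	12762	13119
chr2	12899	13229
chr2	13702	13997
chr2	14451	14608
chr2	16751	16963
chr2	16973	17244
chr2	19364	19546
chr2	21538	21759
chr2	24446	24842
chr2	24811	25037
chr2	25312	25473
chr2	26975	27166
chr2	30732	31079
chr2	33486	33771
chr2	33857	34123
chr2	34485	34646
chr2	38592	38764
chr2	39537	39886
chr2	46897	47290
chr2	48551	48931
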