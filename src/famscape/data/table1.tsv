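parameter	size	total	noninterrupted
P	1	92970
P	2	3048	3048
P	3	0	0
P	4	0	0
P	5	0	0
P	6	0	0
P	7	0	0
P	8	0	0
K2	1	68702
K2	2	13163	11836
K2	3	1299	1223
K2	4	34	34
K2	5	1	1
K2	6	0	0
K2	7	0	0
K2	8	0	0
Leak	1	66611
Leak	2	11873	10305
Leak	3	2133	1569
Leak	4	452	301
Leak	5	92	54
Leak	6	7	6
Leak	7	0	0
Leak	8	0	0
CaS	1	43500
CaS	2	17851	13471
CaS	3	5263	3854
CaS	4	929	765
CaS	5	67	63
CaS	6	4	4
CaS	7	0	0
CaS	8	0	0
SynS	1	38588
SynS	2	16950	11131
SynS	3	6390	3341
SynS	4	1542	832
SynS	5	236	121
SynS	6	10	7
SynS	7	0	0
SynS	8	0	0
h	1	16877
h	2	9895	5545
h	3	6325	2525
h	4	4322	1411
h	5	2703	930
h	6	1285	415
h	7	537	240
h	8	144	144
SynG	1	10551
SynG	2	7047	2830
SynG	3	5086	1276
SynG	4	4124	865
SynG	5	3046	535
SynG	6	1971	483
SynG	7	1061	448
SynG	8	1023	1023
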