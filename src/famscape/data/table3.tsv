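size	high	medium	low
3	690	1002	4633
4	684	1239	2399
5	583	979	1141
6	323	528	434
7	121	233	183
8	35	57	52
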