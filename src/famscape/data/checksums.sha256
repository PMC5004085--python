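e33d10a6b1c550589f011a4fa93e23a9339d897200a3a51e14fc9e12d88180bc  table1.tsv
67a2170a33d7a0d5a4b132c2cc8e05e35cac2865eabafaa16fc0f51d64a21d5e  table2.tsv
7a7a5a14f0d1710a344bef763bae9ed258a2668ca2e2efb339ef52fce4694253  table3.tsv
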