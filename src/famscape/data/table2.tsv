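size	period	spike_frequency	duty_cycle	period_and_spike_frequency_and_duty_cycle	period_and_spike_frequency	period_and_duty_cycle	spike_frequency_and_duty_cycle
2	3759	3679	26449	51	496	3691	4324
3	2188	1597	16102	31	288	1923	1716
4	1286	598	9538	22	154	1087	633
5	656	195	4643	22	96	559	216
6	162	57	1628	0	3	146	37
7	31	9	393	0	0	24	2
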