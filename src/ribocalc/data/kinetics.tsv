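temperature	tau1_ms	tau2_ms	tau3_ms
20	40.0	46.3	2.2
24	26.6	30.7	1.5
30	16.1	18.7	0.9
37	9.1	10.5	0.5
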