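# Published mutant frequency (x1e-5) of adenine 1-bp indels in the rpsL
# reporter region, stratified by adenine-run length, control vs 0.15% KBrO3.
run_length	control	kbro3
2	0.07	0.21
3	0.23	0.56
4	0.02	0.32
5	4.93	10.68
6	19.20	45.94
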