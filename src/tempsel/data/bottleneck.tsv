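start_gen	N
0	32000
200	8000
400	16000
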