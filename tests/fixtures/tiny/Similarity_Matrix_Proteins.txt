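1 0.9 0 0 0
0.9 1 0 0 0
0 0 1 0.7 0
0 0 0.7 1 0
0 0 0 0 1
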