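protein_0
protein_1
protein_2
protein_3
protein_4
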