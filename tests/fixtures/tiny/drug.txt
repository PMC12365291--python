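drug_0
drug_1
drug_2
drug_3
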