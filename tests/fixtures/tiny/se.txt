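side_effect_0
side_effect_1
side_effect_2
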