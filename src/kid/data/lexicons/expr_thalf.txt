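half-life
half life
t(1/2)
t1/2
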