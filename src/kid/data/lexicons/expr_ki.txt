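inhibition constant
inhibitory constant
k(i)
k-i
k(i, app)
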