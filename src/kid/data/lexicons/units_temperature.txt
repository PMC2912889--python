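degrees c
degrees celsius
°c
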