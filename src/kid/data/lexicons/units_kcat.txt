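s(-1)
s-1
sec(-1)
min(-1)
1/s
1/min
per second
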