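m(-1)s(-1)
m(-1) s(-1)
mm(-1)s(-1)
m-1s-1
l/(mol s)
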