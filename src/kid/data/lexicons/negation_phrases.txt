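in absence of
in the absence of
absence of
without
lack of
no
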