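u/mg
units/mg
mu/mg
mumol/min/mg
nmol/min/mg
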