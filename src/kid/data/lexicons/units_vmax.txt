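micromol/min/mg
mumol/min/mg
nmol/min/mg
micromol min(-1) mg(-1)
mumol min(-1) mg(-1)
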