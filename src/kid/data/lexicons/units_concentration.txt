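# shared concentration units (K_M, K_i, K_d, IC_50, S_0.5, K_a)
m
mm
microm
mum
nm
pm
molar
millimolar
micromolar
nanomolar
picomolar
mol/l
mmol/l
micromol/l
nmol/l
mg/ml
micrograms/ml
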