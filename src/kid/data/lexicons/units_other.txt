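# units incompatible with every kinetic category: numbers carrying one are discarded
kg
g
mg
micrograms
ml
kda
km
miles
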