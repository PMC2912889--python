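# K_M expression dictionary (includes common typo/formatting variants)
Michaelis constant
Michaelis constants
Michaelis-Menten constant
Michaelis-Menten constants
Michaelis constant(km)
Michaelis-constant (km)
affinity constant (km)
k(m)
k(m, app)
k(m)app
k(m), app
km ap
k-m
Kappm
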