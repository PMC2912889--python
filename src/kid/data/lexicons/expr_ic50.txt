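ic50
ic(50)
half maximal inhibitory concentration
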