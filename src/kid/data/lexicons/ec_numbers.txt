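# fixture EC-number dictionary
2.7.1.1
2.7.1.2
2.7.1.40
1.1.1.1
1.1.1.27
1.11.1.6
3.5.1.5
3.2.1.17
3.4.21.4
4.2.1.1
3.1.3.1
3.1.1.7
ec 2.7.1.1	2.7.1.1
ec 1.1.1.1	1.1.1.1
ec 3.5.1.5	3.5.1.5
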