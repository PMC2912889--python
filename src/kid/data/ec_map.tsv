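# enzyme name <-> EC number mapping (local stand-in for a database query)
hexokinase	2.7.1.1
glucokinase	2.7.1.2
pyruvate kinase	2.7.1.40
alcohol dehydrogenase	1.1.1.1
lactate dehydrogenase	1.1.1.27
catalase	1.11.1.6
urease	3.5.1.5
lysozyme	3.2.1.17
trypsin	3.4.21.4
carbonic anhydrase	4.2.1.1
alkaline phosphatase	3.1.3.1
acetylcholinesterase	3.1.1.7
amylase	3.2.1.1
amylase	3.2.1.2
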