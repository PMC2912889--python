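# fixture enzyme-name dictionary (toy scale)
hexokinase
glucokinase
alcohol dehydrogenase
lactate dehydrogenase
acetylcholinesterase
trypsin
chymotrypsin
pepsin
catalase
urease
tyrosinase
lysozyme
alkaline phosphatase
glucose phosphatase
pyruvate kinase
adenylate kinase
carbonic anhydrase
xanthine oxidase
amylase
aldolase
enzyme a
enzyme b
IPP	inositol-1,4-bisphosphate 1-phosphatase
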