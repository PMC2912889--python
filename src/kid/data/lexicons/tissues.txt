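# fixture localisation/tissue dictionary (toy scale)
liver
brain
kidney
muscle
heart
cytosol
mitochondria
plasma membrane
serum
erythrocytes
leaf
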