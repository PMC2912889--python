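# fixture organism dictionary (toy scale)
escherichia coli
homo sapiens
human
rat
mouse
rattus norvegicus
saccharomyces cerevisiae
yeast
bacillus subtilis
xenopus
xenopus laevis
arabidopsis thaliana
drosophila melanogaster
zebrafish
rabbit
bovine
wheat
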