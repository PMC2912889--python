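# fixture ligand dictionary (toy scale)
ATP	atp
GTP	gtp
CTP	ctp
ADP	adp
AMP	amp
NAD+	nad+
NADH	nadh
NADPH	nadph
glucose
glucose 6- phosphate	glucose 6-phosphate
fructose
sucrose
lactose
maltose
pyruvate
lactate
ethanol
acetylcholine
urea
hydrogen peroxide
xanthine
phosphoenolpyruvate
citrate
malate
succinate
glutamate
glycine
serine
dopamine
tyrosine
kainic acid
potassium iodide
TPA	12-o-tetradecanoylphorbol-13-acetate
ligand c
ligand d
IPP	isopentenyl diphosphate
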