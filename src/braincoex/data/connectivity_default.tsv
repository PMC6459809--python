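source	target	annotation	citation
PFC	AcbC	glutamatergic projection	rodent-corticostriatal-tracing
PFC	AcbSh	glutamatergic projection	rodent-corticostriatal-tracing
PFC	BLA	glutamatergic projection	rodent-corticoamygdalar-tracing
BLA	PFC	glutamatergic projection	rodent-amygdalocortical-tracing
BLA	AcbC	glutamatergic projection	rodent-amygdalostriatal-tracing
BLA	AcbSh	glutamatergic projection	rodent-amygdalostriatal-tracing
BLA	CeA	glutamatergic projection	rodent-intra-amygdala-tracing
BLA	BNST	glutamatergic projection	rodent-extended-amygdala-tracing
CeA	BNST	GABAergic projection	rodent-extended-amygdala-tracing
BNST	CeA	GABAergic projection	rodent-extended-amygdala-tracing
CeA	VTA	GABAergic projection	rodent-amygdalotegmental-tracing
BNST	VTA	mixed glutamatergic/GABAergic projection	rodent-bnst-vta-tracing
AcbSh	VTA	GABAergic medium spiny neuron projection	rodent-striatotegmental-tracing
AcbC	VTA	GABAergic medium spiny neuron projection	rodent-striatotegmental-tracing
VTA	AcbSh	dopaminergic projection	rodent-mesolimbic-tracing
VTA	AcbC	dopaminergic projection	rodent-mesolimbic-tracing
VTA	PFC	dopaminergic projection	rodent-mesocortical-tracing
VTA	BLA	dopaminergic projection	rodent-mesoamygdalar-tracing
VTA	BNST	dopaminergic projection	rodent-mesolimbic-tracing
VTA	CeA	dopaminergic projection	rodent-mesoamygdalar-tracing
AcbSh	BNST	GABAergic projection	rodent-extended-amygdala-tracing
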