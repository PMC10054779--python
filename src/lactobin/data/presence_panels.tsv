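# lactobin transporter/complex presence panels v1
# Each panel item is a single presence/absence step matched against
# annotation function text (or EC where one is reported in the source data).
panel	item	alternatives
transport	lactate permease	lactate permease
transport	malate permease	malate permease
transport	TRAP transporter	TRAP transporter;TRAP-type;tripartite ATP-independent
transport	maltodextrin ABC transporter	maltodextrin ABC transporter;MdxE;MdxF;MdxG;MdxK
transport	PTS system	PTS system;phosphotransferase system
energy	NADH ubiquinone oxidoreductase (NuoA-N)	7.1.1.2;NADH ubiquinone oxidoreductase;NADH-quinone oxidoreductase
energy	Rnf complex	Rnf complex;electron transport complex protein Rnf
energy	ATP synthase	ATP synthase
energy	ferredoxin hydrogenase (HydEFG)	hydrogenase;HydE;HydF;HydG
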