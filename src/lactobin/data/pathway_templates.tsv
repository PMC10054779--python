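# lactobin pathway templates v1
# step: figure-key number(s); an OR-group of interchangeable enzymes is one
#   step with merged numbering (e.g. 2/3) and its members as alternatives
# alternatives: semicolon-separated EC numbers or function-name fragments
# required: 1 = counted in completeness, 0 = branch/entry step reported only
pathway	product	step	label	alternatives	required
glycolysis	pyruvate	1	glucose-6-phosphate isomerase	5.3.1.9	1
glycolysis	pyruvate	2/3	fructose-6-phosphate 1-kinase	2.7.1.11;2.7.1.90	1
glycolysis	pyruvate	4	fructose-1,6-bisphosphatase	3.1.3.11	0
glycolysis	pyruvate	5	fructose-bisphosphate aldolase	4.1.2.13	1
glycolysis	pyruvate	6	triosephosphate isomerase	5.3.1.1	1
glycolysis	pyruvate	7	glyceraldehyde-3-phosphate dehydrogenase	1.2.1.12	1
glycolysis	pyruvate	8	phosphoglycerate kinase	2.7.2.3	1
glycolysis	pyruvate	9	phosphoglycerate mutase	5.4.2.11	1
glycolysis	pyruvate	10	enolase	4.2.1.11	1
glycolysis	pyruvate	11	pyruvate kinase	2.7.1.40	1
glycolysis	pyruvate	12	phosphoenolpyruvate synthase	2.7.9.2	0
glycolysis	pyruvate	13	L-lactate dehydrogenase	1.1.1.27	0
glycolysis	pyruvate	14/15/16	pyruvate-node oxidation	2.3.1.54;1.2.7.-;1.2.4.1	0
glycolysis	pyruvate	17	phosphate acyltransferase	phosphate acyltransferase	0
glycolysis	pyruvate	18	acetate kinase	2.7.2.1	0
glycolysis	pyruvate	19	acetyl-CoA synthetase (AMP-forming)	6.2.1.1	0
glycolysis	pyruvate	20	aldehyde dehydrogenase	1.2.1.3	0
glycolysis	pyruvate	21	alcohol dehydrogenase	1.1.1.1	0
glycolysis	pyruvate	22	NADP-dependent malic enzyme	1.1.1.40	0
butyrate	butyrate	1	acetyl-CoA C-acetyltransferase	2.3.1.9	1
butyrate	butyrate	2/4/5	3-hydroxybutyryl-CoA dehydrogenase	1.1.1.157;1.1.1.35;1.1.1.36	1
butyrate	butyrate	3/6	crotonyl-CoA formation	4.2.1.17;4.2.1.55	1
butyrate	butyrate	7	butyryl-CoA dehydrogenase complex	Bcd-EtfAB;butyryl-CoA dehydrogenase	1
butyrate	butyrate	8	phosphate acyltransferase	phosphate acyltransferase	1
butyrate	butyrate	9	butyrate kinase	2.7.2.7	1
butyrate	butyrate	10	acetate CoA/acetoacetate CoA-transferase	2.8.3.8;2.8.3.9	0
chorismate	chorismate	1	shikimate/quinate 5-dehydrogenase	1.1.1.282	1
chorismate	chorismate	2	3-dehydroquinate dehydratase II	4.2.1.10	1
chorismate	chorismate	3	shikimate 5-dehydrogenase I alpha	1.1.1.25	1
chorismate	chorismate	4	shikimate kinase I	2.7.1.71	1
chorismate	chorismate	5	5-enolpyruvylshikimate-3-phosphate synthase	2.5.1.19	1
chorismate	chorismate	6	chorismate synthase	4.2.3.5	1
chorismate	chorismate	7	3-deoxy-7-phosphoheptulonate synthase	2.5.1.54	0
chorismate	chorismate	8	3-dehydroquinate synthase	4.2.3.4	0
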