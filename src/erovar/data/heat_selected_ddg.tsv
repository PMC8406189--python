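mutation_code	ddg_mean_kcal_mol	ddg_sd_kcal_mol	original_aa	mutant_aa	position	selection_class
QA119P	3.19	0.0	Q	P	119	heat_selected
AA130E	9.83	0.0	A	E	130	heat_selected
FA131C	4.41	0.0	F	C	131	heat_selected
VA224E	6.91	0.0	V	E	224	heat_selected
VA225E	5.47	0.0	V	E	225	heat_selected
QA240P	5.20	0.0	Q	P	240	heat_selected
KA283E	2.65	0.0	K	E	283	heat_selected
AA359P	4.67	0.0	A	P	359	heat_selected
KA270A	0.01	0.0	K	A	270	control
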