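strain	allele_name	kind	position	start	end	after_position	ref_base	alt_base	inserted_seq	selection_class	reported_protein_change	reported_mw_kda
MTH1	tnaA_A359P	substitution	1075				G	C		heat_selected	A359P	52.8
MT2	tnaA_Q240P	substitution	719				A	C		heat_selected	Q240P	52.8
MT3	tnaA_d106	deletion		187	504					heat_selected	In-frame deletion of 106 aa (positions 63-168)	40.6
MT5	tnaA_V224E	substitution	671				T	A		heat_selected	V224E	52.8
H1	tnaA_ins1	insertion				462			TAT	heat_selected	In-frame insertion of Y between positions 154 and 155	53.0
H2	tnaA_V225E	substitution	674				T	A		heat_selected	V225E	52.8
H3	tnaA_F131C	substitution	392				T	G		heat_selected	F131C	52.7
H4	tnaA_d31	deletion		838	930					heat_selected	In-frame deletion of 31 aa (positions 280-310)	49.3
H6	tnaA_K283E	substitution	847				A	G		heat_selected	K283E	52.8
H8	tnaA_A130E	substitution	389				C	A		heat_selected	A130E	52.8
H9	tnaA_A130E	substitution	389				C	A		heat_selected	A130E	52.8
H10	tnaA_d105_M63S	deletion		188	505					heat_selected	M63S + in-frame deletion of 105 aa (reported 64-168; derived 64-169)	40.6
H11	tnaA_Q119P	substitution	356				A	C		heat_selected	Q119P	52.8
H12	tnaA_V224E	substitution	671				T	A		heat_selected	V224E	52.8
H15	tnaA_G451X	substitution	1355				T	G		heat_selected	Truncation after position 451 (G)	50.4
H16	tnaA_d31	deletion		838	930					heat_selected	In-frame deletion of 31 aa (positions 280-310)	49.3
H17	tnaA_259fs	deletion		777	777					heat_selected	Frameshift: truncation with a 23-aa novel tail after position 258 (Y)	32.2
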