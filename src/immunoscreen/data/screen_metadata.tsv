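screen_id	study_id	cancer_type	setting	library_scale	organism	algorithm	icb_treated
SCR01	STUDY01	skin	in_vitro	genome_scale	mouse	DrugZ	false
SCR02	STUDY01	skin	in_vitro	genome_scale	mouse	DrugZ	false
SCR03	STUDY02	skin	in_vivo	genome_scale	mouse	MAGeCK	false
SCR04	STUDY03	skin	in_vitro	genome_scale	mouse	DrugZ	false
SCR05	STUDY04	skin	in_vitro	focused	mouse	MAGeCK	false
SCR06	STUDY05	skin	in_vitro	genome_scale	mouse	DrugZ	false
SCR07	STUDY06	skin	in_vivo	genome_scale	mouse	RRA	false
SCR08	STUDY07	breast	in_vitro	genome_scale	mouse	MAGeCK	false
SCR09	STUDY07	breast	in_vitro	genome_scale	mouse	MAGeCK	false
SCR10	STUDY08	breast	in_vitro	genome_scale	human	DrugZ	false
SCR11	STUDY09	breast	in_vivo	genome_scale	mouse	casTLE	false
SCR12	STUDY10	colon	in_vitro	genome_scale	mouse	DrugZ	false
SCR13	STUDY10	colon	in_vitro	genome_scale	mouse	DrugZ	false
SCR14	STUDY11	colon	in_vitro	focused	mouse	MAGeCK	false
SCR15	STUDY12	colon	in_vivo	genome_scale	mouse	custom	false
SCR16	STUDY13	pancreas	in_vitro	genome_scale	mouse	DrugZ	false
SCR17	STUDY14	lung	in_vitro	genome_scale	mouse	MAGeCK	false
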