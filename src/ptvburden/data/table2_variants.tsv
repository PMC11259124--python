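variant	hgvs_c	hgvs_p	consequence	n_patients	previously_reported	clinvar_id	acmg
15-85370740-C-T	c.208C>T	p.Gln70Ter	Stop gain	1	This study		Likely pathogenic
15-85383201-C-T	c.691C>T	p.Gln231Ter	Stop gain	5	This study		Likely pathogenic
15-85400805-ACCCCAGGT-A	c.2841_2848del	p.Gly948GlufsTer3	Frameshift	1	This study		Likely pathogenic
15-85401144-C-T	c.3175C>T	p.Arg1059Ter	Stop gain	1	Almomani et al. (2016), Lopes et al. (2021), van Velzen et al. (2018)	VCV000488984.18	Pathogenic
15-85401309-C-T	c.3340C>T	p.Arg1114Ter	Stop gain	1		VCV001414127.4	Pathogenic
15-85401376-AGCCCTCCCAAGAGGAGAAGTTCCCAGGG-A	c.3409_3436del	p.Pro1137ArgfsTer3	Frameshift	4	Dai et al. (2022)		Pathogenic
15-85401543-T-TC	c.3580dup	p.Arg1194ProfsTer62	Frameshift	3		VCV000636490.6	Pathogenic
15-85401599-GGA-G	c.3635_3636del	p.Arg1212ThrfsTer43	Frameshift	2	This study		Likely pathogenic
15-85401660-G-T	c.3691G>T	p.Glu1231Ter	Stop gain	1	This study		Likely pathogenic
15-85402623-T-G	c.3965+2T>G	p.?	Canonical splice site	1	This study		Likely pathogenic
15-85405928-T-TG	c.4198dup	p.Asp1400GlyfsTer58	Frameshift	1	Dai et al. (2022)		Pathogenic
15-85405970-C-T	c.4234C>T	p.Arg1412Ter	Stop gain	6	Dai et al. (2022)	VCV000636381.9	Pathogenic
15-85410547-G-A	c.4724-1G>A	p.?	Canonical splice site	7		VCV001498045.5	Pathogenic
15-85410592-C-T	c.4768C>T	p.Arg1590Ter	Stop gain	2	Lopes et al. (2021)	VCV000620214.3	Pathogenic
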