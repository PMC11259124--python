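hgvs_c	hgvs_p	hcmp_n	gnomad_eas_n	koges_n	kova2_n	exome_n
c.208C>T	p.Gln70Ter	1
c.417del	p.Tyr140ThrfsTer33		2
c.589G>T	p.Glu197Ter		1
c.691C>T	p.Gln231Ter	5	2	2	2	3
c.1170del	p.Ser391LeufsTer25				1
c.1360del	p.Ala454LeufsTer17		1
c.1417del	p.Gln473SerfsTer30		1
c.1627C>T	p.Gln543Ter		1
c.2455C>T	p.Arg819Ter			1
c.2509C>T	p.Gln837Ter		1
c.2841_2848del	p.Gly948GlufsTer3	1
c.3105T>A	p.Cys1035Ter		1
c.3175C>T	p.Arg1059Ter	1
c.3230dup	p.Asp1077GlufsTer14				1
c.3340C>T	p.Arg1114Ter	1			1
c.3409_3436del	p.Pro1137ArgfsTer3	4	1	1	1	1
c.3580del	p.Arg1194GlyfsTer78		1
c.3580dup	p.Arg1194ProfsTer62	3	1
c.3635_3636del	p.Arg1212ThrfsTer43	2	1	1		1
c.3691G>T	p.Glu1231Ter	1
c.3965+2T>G	p.?	1
c.4198dup	p.Asp1400GlyfsTer58	1
c.4235_4244del	p.Arg1412HisfsTer63		1
c.4234C>T	p.Arg1412Ter	6			3	1
c.4500-1G>A	p.?				1
c.4724-1G>A	p.?	7				2
c.4768C>T	p.Arg1590Ter	2
c.4772+1G>T	p.?		1
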