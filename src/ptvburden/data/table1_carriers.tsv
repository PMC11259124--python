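patient_id	hgvs_c	hgvs_p	age	sex	primary_phenotype	additional_phenotype
Patient 1	c.208C>T	p.Gln70Ter	58	Male	LVH
Patient 2	c.691C>T	p.Gln231Ter	78	Male	LVH
Patient 3	c.691C>T	p.Gln231Ter	53	Male	LVH
Patient 4	c.691C>T	p.Gln231Ter	66	Male	LVH
Patient 5	c.691C>T	p.Gln231Ter	26	Male	LVH
Patient 6	c.691C>T	p.Gln231Ter	70	Male	LVH	Syncope, pain
Patient 7	c.2841_2848del	p.Gly948GlufsTer3	64	Male	LVH
Patient 8	c.3175C>T	p.Arg1059Ter	65	Male	LVH
Patient 9	c.3340C>T	p.Arg1114Ter	24	Male	LVH	Left ventricular diastolic dysfunction
Patient 10	c.3409_3436del	p.Pro1137ArgfsTer3	32	Male	LVH	Arrhythmias
Patient 11	c.3409_3436del	p.Pro1137ArgfsTer3	34	Male	LVH	Proteinuria
Patient 13	c.3409_3436del	p.Pro1137ArgfsTer3	31	Male	LVH
Patient 14	c.3409_3436del	p.Pro1137ArgfsTer3	63	Female	LVH	Arrhythmias
Patient 15	c.3580dup	p.Arg1194ProfsTer62	47	Male	LVH
Patient 16	c.3580dup	p.Arg1194ProfsTer62	51	Male	LVH	Hypertension
Patient 17	c.3580dup	p.Arg1194ProfsTer62	40	Male	LVH	Heart failure
Patient 18	c.3635_3636del	p.Arg1212ThrfsTer43	51	Male	LVH	Hypertension
Patient 19	c.3635_3636del	p.Arg1212ThrfsTer43	70	Male	LVH
Patient 20	c.3691G>T	p.Glu1231Ter	43	Female	LVH	Arrhythmia, nerve conduction abnormalities
Patient 21	c.3965+2T>G	p.?	61	Male	LVH
Patient 22	c.4198dup	p.Asp1400GlyfsTer58	63	Male	LVH
Patient 23	c.4199del	p.Asp1400AlafsTer8	77	Male	LVH	Proteinuria
Patient 24	c.4234C>T	p.Arg1412Ter	50	Male	LVH	Heart failure
Patient 25	c.4234C>T	p.Arg1412Ter	51	Male	LVH	Pain
Patient 27	c.4234C>T	p.Arg1412Ter	82	Male	LVH
Patient 28	c.4234C>T	p.Arg1412Ter	41	Male	LVH
Patient 29	c.4234C>T	p.Arg1412Ter	59	Male	LVH
Patient 30	c.4724-1G>A	p.?	55	Male	LVH	Syncope
Patient 31	c.4724-1G>A	p.?	58	Female	LVH
Patient 32	c.4724-1G>A	p.?	48	Male	LVH
Patient 33	c.4724-1G>A	p.?	67	Male	LVH	Heart failure
Patient 34	c.4724-1G>A	p.?	51	Male	LVH	Syncope
Patient 35	c.4724-1G>A	p.?	39	Male	LVH
Patient 36	c.4724-1G>A	p.?	87	Female	LVH
Patient 37	c.4768C>T	p.Arg1590Ter	28	Male	LVH
Patient 38	c.4768C>T	p.Arg1590Ter	17	Male	LVH	Syncope
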