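patient_id	followup_years	ecg	lvh_morphology	max_wall_thickness_mm	lvef_percent
Patient 1	2	LVH(+)	Concentric	13	70
Patient 2	11	LVH(+), RBBB	Asymmetric	28	69
Patient 3	14	LVH(+)	Concentric	19.2	64
Patient 5	<1	LVH(+)	Asymmetric	28	67
Patient 6	2	LVH(+)	Atypical	20	67
Patient 7		LVH(+)	Atypical	21	63
Patient 11	2	LVH(+)	Atypical	28.6	58
Patient 12	2	LVH(+)	Concentric	12	56
Patient 13		LVH(+)	Atypical	14	69
Patient 14	3	LVH(+)	Atypical	15	58
Patient 15	7	LVH(+)	Asymmetric	21	81
Patient 16	<1	LVH(+)	Asymmetric	23	64
Patient 18	2	LVH(+)	Asymmetric	26	59
Patient 21	12	LVH(-)	Atypical	20	20.3
Patient 22	2	LVH(+)	Atypical	19	57
Patient 24	2	LVH(+)	Atypical	27	60
Patient 25	3	LVH(+)	Asymmetric	19	74
Patient 26	6	LVH(+)	Atypical	15	71
Patient 27	5	LVH(+)	Asymmetric	19.3	72
Patient 30	10	LVH(+)	Atypical	20	65
Patient 33	6	LVH(+)	Asymmetric	27	79
Patient 34	16	LVH(+)	Atypical	14	64
Patient 35	8	LVH(+)	Concentric	13.6	70
Patient 36	1	LVH(-)	Concentric	16	62
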