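antibody_id	gene	tissue	cell_type	sample_kind	cancer_type	patient_id	intensity	quantity
HPA034966	HPA034966-target	breast	glandular cells	normal			Moderate	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt01	Strong	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt02	Moderate	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt03	Strong	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt04	Strong	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt05	Moderate	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt06	Moderate	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt07	Moderate	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt08	Moderate	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt09	Moderate	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt10	Moderate	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt11	Moderate	>75%
HPA034966	HPA034966-target	breast		cancer	Breast cancer	pt12	Moderate	>75%
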