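id	family	gpcr_class
REF_FMRFamide_receptor	FMRFamide receptor	A
REF_myosuppressin_receptor	myosuppressin receptor	A
REF_allatostatin-A_receptor	allatostatin-A receptor	A
REF_proctolin_receptor	proctolin receptor	A
REF_CCAP_receptor	CCAP receptor	A
REF_ACP_receptor	ACP receptor	A
REF_RPCH_receptor	RPCH receptor	A
REF_vasopressin-neurophysin_receptor	vasopressin-neurophysin receptor	A
REF_CCHamide_receptor	CCHamide receptor	A
REF_TRH_receptor	TRH receptor	A
REF_SIFamide_receptor	SIFamide receptor	A
REF_tachykinin_receptor	tachykinin receptor	A
REF_NPF_receptor	NPF receptor	A
REF_sNPF_receptor	sNPF receptor	A
REF_GPA2-GPB5_receptor	GPA2/GPB5 receptor	A
REF_DH31_receptor	DH31 receptor	B
REF_DH44_receptor	DH44 receptor	B
REF_PDH_receptor	PDH receptor	B
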