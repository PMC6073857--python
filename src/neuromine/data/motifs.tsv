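family	pattern	min_matches
AKH/RPCH	^pQLNFSPGWamide$	1
corazonin	^pQTFQYSRGWTNamide$	1
ACP	^pQITFSRSWVPQamide$	1
myosuppressin	^pQDLDHVFLRFamide$	1
CCAP	^PFCNAFTGCamide$	1
proctolin	^RYLPT$	1
SIFamide	GYRKPPFNGSIFamide$	1
sulfakinin	HMRFamide$	1
FMRFamide-like	NFLRFamide$	1
sNPF	SLRFamide$	1
NPF	APRFamide$	1
tachykinin	FLGMRamide$	1
allatostatin-A	FGLamide$	1
kinin	SWGamide$	1
RYamide	RYamide$	1
DH31	AGGPamide$	1
PDH	NSELINS.*amide$	1
orcokinin	NFDEIDRS	2
CHH/MIH/GIH	^PATEYPTIWD	1
GPA2	^HSIECAHAHA	1
GPB5	^YFDTNDDWSF	1
phoenixin	^(LSSVPIIAMYENSTETDHPF|NSSPEYDMPIMMDW)amide$	1
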