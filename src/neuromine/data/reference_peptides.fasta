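>rpch_peptide1
QLNFSPGW
>corazonin_peptide1
QTFQYSRGWTN
>acp_peptide1
QITFSRSWVPQ
>ccap_peptide1
PFCNAFTGC
>proctolin_peptide1
RYLPT
>sifamide_peptide1
GYRKPPFNGSIF
>myosuppressin_peptide1
QDLDHVFLRF
>tachykinin_peptide1
APSGFLGMR
>allatostatin_a_peptide1
APYAFGL
>allatostatin_a_peptide2
AGPYSFGL
>allatostatin_a_peptide3
PRDYAFGL
>fmrfamide_peptide1
DGNFLRF
>fmrfamide_peptide2
GNSNFLRF
>ryamide_peptide1
FVGGSRY
>ryamide_peptide2
SGFYANRY
>snpf_peptide1
APALSLRF
>npf_peptide1
KPDPSQLANMAEALKYLQELDKYYSQVSAPRF
>kinin_peptide1
DPAFSSWG
>sulfakinin_peptide1
GGDDQFDDYGHMRF
>pdh_peptide1
NSELINSLLGLPKVMNDA
>orcokinin_peptide1
NFDEIDRSGFGFN
>orcokinin_peptide2
NFDEIDRSSFGFN
>orcokinin_peptide3
NFDEIDRSGFGFV
>dh31_peptide1
GLDLGLSRGFSGSQAAKHLMGLAAANYAGGP
>chh_like_peptide1
PATEYPTIWDVAEPILLAMEFSHIYECPEFENAEFECPLPPNSCPSCAMYCVLTFPLPCI
>gpa2_peptide1
HSIECAHAHANPCTNEHVVTLPMNDAICEHFHIFHWIVACDDHYFLNTMSAIDEMPTANY
HDTNCTNCCNAVPCMLHDCIISICPIFWFFYNFTWTH
>gpb5_peptide1
YFDTNDDWSFPWCHCCVYNHFMMTTNEFNSSYCLSWCNNVFYALVMFIMACFFVWPSSSI
FHEPIDTPDHYSHSHCSTTYHDMLAHIDCECVVNSCHYYVAMVTYAHFEAHSWNYYSAYI
SSWIFP
>pnx_peptide1
LSSVPIIAMYENSTETDHPF
>pnx_peptide2
NSSPEYDMPIMMDW
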