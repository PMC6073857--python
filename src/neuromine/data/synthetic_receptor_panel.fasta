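>REF_FMRFamide_receptor
MDEKSNPSEEDHPEGEHNSQSNNQLLFVVVIVFFFVFVILVLVLVVIPTTNSPPEEPQES
QIFVFIFFIFVIFLIFILFLLLVVTSPDNGHSQGHQQPVIVLIILFVVILILILLLIFFF
VDRYHSNDNQTPQSPLILFFIFFFVILLVVIFFFFLLVEQEEQPNNPEEEGQIIVIFFIF
ILVFFVFFFLLIVLVGQTTNTDEHQPNTDFIFFIIVVVFFFVLIILIVFFFFGNQDEGTG
PGGPQEIILLLVVVIFFILVLFLLLVVLFHEPSTHPQQQPHDQNETPGPQHPTS
>REF_myosuppressin_receptor
MEDKQHQDHSTPPEGHSSGGDTILFVLLVIFIFLFFVLVVVLVVIPGHEPQDHHEEGGNI
LLILIFFFFILIIILVFLLVFISEQPDNNNNPGGNPIFLLLVLFLVFVILVLLLFIFVLD
RYDPQQTPETPEQILLFVFLLLILILVVFIIIVFLINSNPPENPHQHEDPVVIFFLVVIV
FIFVVIIFIFLLLGNSTHNTSHNENEGLLFIIVLIIIFFFFLFVVVFFFIGDNSTEPQGT
NNDGFLIFFLVFVVVVLVVLVIIVILITTPTDHDNGDESPQNDPPHSHPSPH
>REF_allatostatin-A_receptor
MQNKQHGHHPGGNNENGEEDGHGEGHFVFFIFLLLVFIVVVIVFFVLLVSDGNGGEENEN
DENVVFVIVIFIILLIVILFFVLVLLNPGEEEGETNSENQVFFVVFVFLFVVIVLLVFVL
IVIDRYHDQDQQENQTDVLVFVVLVIIVIIILIVLLFIVFEQTESSNGNHGQQDILLLIV
IILLILIFIVIFVIIVLEPGNQEPQTNHSPDIVLFFVVVFILVFVLVVIFVVIFGHDENH
TTGSNDNDFLLLLLFILFIILVVVVFFVFVINEPQGTQPPSSDTTDGHPHDDNPQD
>REF_proctolin_receptor
MEDKTPPTNEPPTPQPNENTHLVLFVFLFLLIVILLFIVFFFVFGGTDHSDENQTQTNVF
FILFVFLFILLLFVVVLVVIFDTHEEHQQPEQPNDFLFIFLLFIFLVVLLIVVVVIVFDR
YNSQPHPTPEPEVVIVFFVLLLLFLLLIVIILILVNEDEGQEQDQPPSQLLFVLLFILLI
FFLFLILFFVFIPNGESNQGDNTGPSIFFLFILFIFFVIFVLIFLVLFLEQQHESHQHHP
NQEIFILFVLIVFVFLLVVIFFFVIIEPQENEDQNTEDQTESGHGNGPNSS
>REF_CCAP_receptor
MDNKHSQQDTQTGPPEQESDSPQPDQTDLVILIVFFFIIIFLVVIIIIFFFNQSDTTQSE
EQPTELVVLVVFVVIFFILLIIFFFLVVTQGTGDSENETGSQVFIFVILIVLLIVIVLLL
VLIVVDRYPSNPQSNQTPGFFIFIIVILVIIFLILIVILVVLQSHDQNDDTSGDGTILVV
LVFLLFILLIFVFFFVVIIPSTPQNGPSQNQGNVVFLFLLIIILIFILLFVFLLFVDNHS
DNSTENPNPQIFLLIIFILFVFVFLFILLVLVIHNGQTNNDHQQGGGPPTTNNNGDGS
>REF_ACP_receptor
MSDKQEQTSHTQNEEHDPNGTPQDNVILLIIIVVFFVLILFLVFLFVVGETEENSHHEHP
DGVIVFFFVLIFFILLVLFIFLFVISEDEQHSHPPDTDGIFVVIFVVIIIIIVLLLILFI
LIDRYPPQHTDESGHDIFVFVLFVVFLFLIIILLIFLFISQGEQTHQNHDHGEIFLILLV
LFILFLVFILVIVLLVEGTEGEDSNEPTTTIVVVVFIILLIVFILILIIFIIITQHNENS
DPHDTEHIFIVIFIVILLVLLLLVLIFVIFDQNQTEDQHNPDEEETSENQQDEHQ
>REF_RPCH_receptor
MDSKNDGPDHQSQNNTQSGNTQQIIIFLFIIVFLLVFVVFLLIFFIDDQGQQEDGNGGSS
FLVFIFVLLFFLIFFVILVILFLNPDQSQPHQPDDSGIVLVILVIIIFLVIIIVFIFIVI
DRYENTTQHTSDSGVVLLIVVIFFLVILLVLIFLLLIPDDHTPSPNSEGGTIIFIIILFL
IVFLFLLLIFVLFIGSGHTTQSQQNDNDLLIFLIVFFLLVIIFVIVIIVIFHSDTPQTPT
QNDHGIFVLLFVFFFLLVIVVILVFLVVTTESEQHGDGNGEPHSEPGPPGESE
>REF_vasopressin-neurophysin_receptor
MTPKENPHSEGPEQHNEEQPSPQHEDQFLLIFIVLIVLVLILFLFVFIFIESQGDGETPN
NNDHVIFIVFIFIVIIVVIILVLFIILGDTSTHDESTQDHPFFILIIIVIFFFLIFFLIL
VLFLDRYETTEHEPNDHTFFVFFVFILVLIFLLFFLLFIFFTTQQENESDGGPQDVVLLL
FLLILLIVFFLLIIFFFFPQGTGHQEPDGEESVVLVLLFIFIFLLILFLLLFFLVQTGST
HTQDQGTNHLVFVLFFVLIVLILVLFVLILILHEDHTPSESDQGTNGNSGQSTPGDG
>REF_CCHamide_receptor
MNPKDPEPSNSEEDTTNQEPGTSPFVLVLVVIVFLVIFFVVVFIVLFSPSQQQHGPQHPH
HVVVLVFVFIVVILLLFILIVVLFSNNQHGSEDEGGPSFVFLIFIVFIFFIVIVVIVFFI
LDRYDQETQHQDTGQVVVLLILVLLIIILLIVVVVILLPPEEPQTPGNQGHHILLIFFIF
IFLLFLVIVVFVIIFGETQNHDEPHENGSFLILIIILIFVIILLLVLLVIVLGNQPHPQH
NGNDSSVIIVIVVVFLVFIVFLVIFLLLIDDPQHNGGPNGDDQPNGQHGTNSGE
>REF_TRH_receptor
MESKGPHNETDQPQGSEDDEDEFILLVFLFFLVLFLLVLLIFFVFHTNGEQDNDNHPDTL
VLVLLVFFVFLFFILFVVILVLPDTHNQTQPEEQGGFFFIIFILLIFLVILLVFFVFFLD
RYENETNSSGPDPIFVLIFFIVFILLFILLIVLFFVDPGPPQTQQSQGNHFLLFIFVLVL
IVFLLIFFFFFVFNQPDEEHPPENENGIVILIFFFFVFLVILLVVIFIILQHHNSHGTST
SHDHLLLIVFFVILLVILFFVIIILIFEGDEQSTHSNPDNGGSDTGNGGHNN
>REF_SIFamide_receptor
MNSKTTPTTETTDGPGEDNHSDDENHFFVLLVVVIILVIIFLFIIFFIIGSNPPGEPNEH
PDEIVFLLVFVVLLIFFFIFLFVFVVEQHQDSDQPSPDNQIIFVFFFIFIIVLVFFVVLV
FFIDRYHQEHDSTDNNEFLVFIIVLLIFLVVLFFIVFVFLSDEETNHTEDNHPDFVLIII
LLFFVIIFIFLFVIVFLQEETDDNPPQPHDDVILVLLIIIIFIVVLLILLLIIITSPSTP
QQTEDQSHFILLVVIFFLFLFVIVLLIFVVVQQHEDQTHHDQSHQEEHQNQNGSPP
>REF_tachykinin_receptor
MTTKHPPSPHPDSGQTDGTTGGHPGFLVIILFVFVLLIFLVVLVFLIFEQDSNSGDESNN
PTIIVIIIFFLVIIFVIIIFVFVLITSTTTPPQGESQTDLFVVIFLLVVIVIIVFIIILL
VLDRYSGQENQGGGGPFIVLVLLVFLFFIVFLILVVFLLNDPHNPHQHEQTEPVVIILFL
IFFLVFLFLVVFLIFFGDHTQTQQTPHNGQLFFVLLVVLLIFFIFLFVLVFIFNHESETD
TEDNETPFLFIILVFLFFLVVILLILVLIVQPGTGTGTTETTESGGTHHESGDSP
>REF_NPF_receptor
MQEKPPDGNDNQHPTPNNQGTGQHHSQGVFIILVLLIIFLLIFIVVFIVLIGDHSSTDST
DGPPGFFIILLFVIVFILVLLIFFLVIISGHSSPNGDNHNQNLVLFLLILLIILIIVFFI
FIILIDRYNTQEGSGPQSTLFVIFVLLVFVVVILIIVILIVVPTHSSQQEDHGSTHIVFL
FVVLFIVFLFVILFVLVVFGGHHDEDTNTPHEEVFLLLILIVIFIVLLVLIILIIITQHG
HNQDHDNHESIVIVVLILLILIIFVLLIILLLVEHGNGGTDESQQGGSHTTDNNQHHP
>REF_sNPF_receptor
MHEKDGTDENSPQTEHQTNEGNPDLLVIFIVVILIIFFVIFVILLILSESSEEHNTGHGE
HVLFVLVVVFLVIFIIVFFFLLLFDQPGTQPPDNPTSPLFVFFILLIIVLILFIILILFV
FDRYNTTHSQPGNGNILVVFVVFLVLFFFFIVLLLLIFGTHTEPNSESTGQHIFLFIIFF
IVVIVIIFFIFFFVFHQGTPDDPNSPNDGILLLVLVVVVILLLVVFFFFFFLPGTNNQGP
THGPQHILLLIVVLVFLVFVFLFVIIVLFSQPDPDEPGQSTTPTEHQHNGHGQG
>REF_GPA2-GPB5_receptor
MESKHDDDTTQNTTDTNHQEGSQSQDHDNSPTPHNHEDDGHGEHNTHSSGQTPQQEGPDP
PSPSHQQEDTEQGHDGQHDNDGHQGGTTSTPQTQPQPQGGEGHQNPTGGTQHSSQDSEGD
QTTTSQQTGDGEPEDHQQEHSQQNQGPDDPQTEHDGDHPPQNDTEGQHSSTSPTTNHNPD
QNPTSNTQEDTDTDGDQHHPPNSQPQEQHSQQDNHPGEDDHQGQQGPENHHENGGSPTPE
DDGNTSHPQHGDHGETNNNNQGNPGDNNNPHDESNQSSDDGTDGPQHPEQNEEPSTGNET
DGGPDHTGHTGDGHQSSHPQVVLIFFLLFLIFFIILLIIVIFIQDEENQSGGNTEHSFVL
LIFVVLIFVIIIIVVFIFLIHQEDEDDPHTGHSHFFVIVFLILFVILFIFILLILILDRY
NHHSGGSSSNTVVLIVVFILLLILFFLFLFVIILHPQTTQETQHHNHGLIIFLIFIILIL
ILLILLILFLFQSDETDDTPETTPEILFVIVLIFLFLILIFLVILIIITGPENNSSSHNT
ENVILVVFLFFIIVIVIILVILVFVETEDSESQTPDGTGPDGTHTQNHSE
>REF_DH31_receptor
MSEKSGDTDPNGDHSSQTSGNTQPDHQSQEVFLFIVVLIIILFFIIIFVLLFFCGDPDSC
SETTTGHILVFLILFIFLLIFIIFFVILIFGEQNETDDQHQPNNLLLFVLVFFFFIFVLV
FLIILFIEGDSSSPQTQDDDHVFILIIVVFLLFVIIIFLFLLFFESTEHQEDHDQTNDLV
VFLVILIILIVIFVIVIIFFITDNDHHEHDQPEPDLVIVILLLVFFVFFFIFILVVIIQQ
SENPTNQTNPTSFVLLFVVVLLFLVIIIVIIVVVFPQGSQNHTPTTDNTPGGTDPNNNEG
>REF_DH44_receptor
MDPKNHGENSPGQNPNTGEEEPTGPSDSEPSEFFVFVLFILIFFFIVILIIILIICDEGQ
TCTSETENPIIFVLFFLLLVFIILLLIFLIVIEDETQDSGGNEHSDLFIIIVVILVFVLV
VFILIVLIVNQSSTNEPSTEGGGVIIIILLVIILFVFVFIVLIVLIHGPQPSEDHNNHPS
IVFILILLILVFFVVFVFLLLVVHENGHDTDDPEQHQLLIILLFIFIILIVIFVVLVILF
PNPTNDSSQTENQSIFVIILFFLIIIFILVIIVLFIFTPTPNPQTSHHTPEQDDDDSTHE
DT
>REF_PDH_receptor
MSPKHQPEHEQNDSTDTHDDQGTHEHNDVVIFLFFFFFLLILILLLILLLICDGHQSCNS
NSGEPIILLIFFFFLVVLLVFLFVFFIIHTQSTNNNNTSPESIFLIIVLIFVLLIIIVLV
VLLVFEGEPHQDDQPHHQQLVVLIVVVLVIIFIFFIVIIILITNGPSSDQNTTEHPVLFF
FLLVVILFLVLLIFLLFLVNTETNTQHGHGEENILVLFVIVVFIILIVIVLVVLLLDDPP
NEPNDTGDEHFVIFLFFVIVVLVIILILVLIFIHPSDSDPPETQPSPQPHQTDQTSPH
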