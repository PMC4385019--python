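id	consensus	annotation
ABRELATERD1	ACGTG	ABA-responsive element core, early responsive to dehydration
ABRERATCAL	MACGYGB	ABA-responsive element related to calcium signaling
ABREOSRAB21	ACGTSSSC	ABA-responsive element of rice rab21 promoter
ACGTABREMOTIFA2OSEM	ACGTGKC	ABA-responsive element motif A2 of rice Em promoter
ABREATCONSENSUS	YACGTGGC	ABA-responsive element consensus
ABREZMRAB28	CCACGTGG	ABA-responsive element of maize rab28 promoter
ABREATRD22	RYACGTGGYR	ABA-responsive element of rd22-type promoters
ABREMOTIFAOSOSEM	TACGTGTC	ABA-responsive element motif A of rice Em promoter
ABREA2HVA1	CCTACGTGGC	ABA-responsive element A2 of barley HVA1 promoter
ABREBNNAPA	CGCCACGTGTC	ABA-responsive element of napin promoter
ABRETAEM	GGACACGTGGC	ABA-responsive element of wheat Em promoter
ABADESI2	GGACGCGTGGC	ABA-responsive desiccation element
ACGTABOX	TACGTA	ACGT A-box, light and seed expression
ACGTSEED3	GTACGTG	ACGT element of seed storage promoters
TATABOX3	TATTAAT	TATA box variant
TATABOX5	TTATTT	TATA box variant
GT1CORE	GGTTAA	GT-1 binding site core, light regulation
GT1CONSENSUS	GRWAAW	GT-1 consensus binding site
ARFAT	TGTCTC	auxin response factor binding site
RYREPEATGMGY2	CATGCAT	RY repeat of seed storage promoters
RYREPEAT4	TCCATGCATGCAC	RY repeat tetramer element
AMYBOX1	TAACARA	amylase box, gibberellin response
GAREAT	TAACAAR	gibberellin-responsive element
PYRIMIDINEBOXOSRAMY1A	CCTTTT	pyrimidine box of rice amylase promoter
CAATBOX1	CAAT	CAAT box
CCAATBOX1	CCAAT	CCAAT box
GATABOX	GATA	GATA box, light-regulated promoters
IBOXCORE	GATAA	I-box core, light-regulated promoters
DOFCOREZM	AAAG	Dof protein core binding site
WBOXNTERF3	TGACY	W box, WRKY binding, wounding response
WRKY71OS	TGAC	WRKY71 binding site, defense signaling
MYBCORE	CNGTTR	MYB core binding site, drought response
MYCCONSENSUSAT	CANNTG	MYC consensus, dehydration response
EBOXBNNAPA	CACCTG	E-box of napin promoter
HEXMOTIFTAH3H4	ACGTCA	hexamer motif of histone promoters
LTRE1HVBLT49	CCGAAA	low-temperature-responsive element
LTRECOREATCOR15	CCGAC	low-temperature-responsive element core
DRECRTCOREAT	RCCGAC	dehydration-responsive element / C-repeat core
CBFHV	RYCGTG	CBF binding site of barley
CGCGBOXAT	VCGCGB	CGCG box, calmodulin-binding signaling
SITEIIATCYTC	TGGGCY	site II element of cytochrome promoters
TELOBOXATEEF1AA1	AAACCCTAA	telo box of translation elongation factor promoters
CURECORECR	GTAC	copper response element core
PALBOXAPC	CCGTCC	PAL box A, phenylpropanoid pathway
ROOTMOTIFTAPOX1	ATATT	root-expression motif
POLLEN1LELAT52	AGAAA	pollen-specific activation element
CACTFTPPCA1	YACT	mesophyll expression module CACT
ANAERO1CONSENSUS	AAACAAA	anaerobic induction element
PREATPRODH	ACTCAT	proline dehydrogenase hypoosmolarity element
SURECOREATSULTR11	GAGAC	sulfur-responsive element core
BIHD1OS	TGTCA	BELL homeodomain binding site, disease resistance
OSE2ROOTNODULE	CTCTT	organ-specific element of root nodules
SORLIP1AT	GCCAC	sequence over-represented in light-induced promoters
C1MOTIFZMBZ2	GGATAAGGGTTTAGC	C1 motif of maize bz2 promoter
GBOXSORBCS1	GACACGTGGCG	G box of sorghum rbcS1 promoter
EVENINGAT	AAAATATCT	evening element, circadian regulation
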