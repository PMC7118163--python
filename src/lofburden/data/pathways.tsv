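pathway	gene
base_excision_repair	RFC1
base_excision_repair	RFC2
base_excision_repair	RFC3
base_excision_repair	RFC4
base_excision_repair	RFC5
base_excision_repair	XRCC1
base_excision_repair	PCNA
base_excision_repair	PARP1
base_excision_repair	PARP2
base_excision_repair	APEX1
base_excision_repair	FEN1
base_excision_repair	POLE
base_excision_repair	POLD1
base_excision_repair	LIG3
base_excision_repair	OGG1
base_excision_repair	UNG
base_excision_repair	SMUG1
base_excision_repair	MBD4
base_excision_repair	TDG
base_excision_repair	MUTYH
base_excision_repair	NTHL1
base_excision_repair	MPG
base_excision_repair	NEIL1
base_excision_repair	NEIL2
base_excision_repair	NEIL3
base_excision_repair	APEX2
base_excision_repair	PNKP
base_excision_repair	APLF
base_excision_repair	PARP3
base_excision_repair	LIG1
mismatch_repair	RFC1
mismatch_repair	RFC2
mismatch_repair	RFC3
mismatch_repair	RFC4
mismatch_repair	RFC5
mismatch_repair	PCNA
mismatch_repair	MSH3
mismatch_repair	MSH4
mismatch_repair	MSH5
mismatch_repair	MLH3
mismatch_repair	PMS1
mismatch_repair	PMS2P3
mismatch_repair	EXO1
mismatch_repair	POLD1
nucleotide_excision_repair	RPA1
nucleotide_excision_repair	RPA2
nucleotide_excision_repair	RPA3
nucleotide_excision_repair	RPA4
nucleotide_excision_repair	RFC1
nucleotide_excision_repair	RFC2
nucleotide_excision_repair	RFC3
nucleotide_excision_repair	RFC4
nucleotide_excision_repair	RFC5
nucleotide_excision_repair	PCNA
nucleotide_excision_repair	ERCC1
nucleotide_excision_repair	ERCC4
nucleotide_excision_repair	ERCC2
nucleotide_excision_repair	ERCC5
nucleotide_excision_repair	XPC
nucleotide_excision_repair	ERCC6
nucleotide_excision_repair	GTF2H2
nucleotide_excision_repair	ERCC3
nucleotide_excision_repair	XPA
nucleotide_excision_repair	RAD23B
nucleotide_excision_repair	POLE
nucleotide_excision_repair	POLD1
nucleotide_excision_repair	RAD23A
nucleotide_excision_repair	LIG3
nucleotide_excision_repair	CETN2
nucleotide_excision_repair	DDB1
nucleotide_excision_repair	DDB2
nucleotide_excision_repair	GTF2H1
nucleotide_excision_repair	GTF2H3
nucleotide_excision_repair	GTF2H4
nucleotide_excision_repair	GTF2H5
nucleotide_excision_repair	CDK7
nucleotide_excision_repair	CCNH
nucleotide_excision_repair	MNAT1
nucleotide_excision_repair	LIG1
nucleotide_excision_repair	ERCC8
nucleotide_excision_repair	UVSSA
nucleotide_excision_repair	XAB2
nucleotide_excision_repair	MMS19
homologous_recombination_repair	ATM
homologous_recombination_repair	RPA1
homologous_recombination_repair	RPA2
homologous_recombination_repair	RPA3
homologous_recombination_repair	RPA4
homologous_recombination_repair	RAD51
homologous_recombination_repair	NBN
homologous_recombination_repair	RAD50
homologous_recombination_repair	CHEK2
homologous_recombination_repair	PALB2
homologous_recombination_repair	MUS81
homologous_recombination_repair	EME1
homologous_recombination_repair	MRE11A
homologous_recombination_repair	RAD52
homologous_recombination_repair	RAD51B
homologous_recombination_repair	DMC1
homologous_recombination_repair	XRCC2
homologous_recombination_repair	XRCC3
homologous_recombination_repair	RAD54L
homologous_recombination_repair	RAD54B
homologous_recombination_repair	SHFM1
homologous_recombination_repair	RBBP8
homologous_recombination_repair	SLX1A
homologous_recombination_repair	SLX1B
homologous_recombination_repair	GEN1
fanconi_anaemia	ATR
fanconi_anaemia	ERCC1
fanconi_anaemia	FANCA
fanconi_anaemia	FANCB
fanconi_anaemia	FANCC
fanconi_anaemia	FANCD2
fanconi_anaemia	FANCE
fanconi_anaemia	FANCF
fanconi_anaemia	FANCG
fanconi_anaemia	FANCI
fanconi_anaemia	FANCL
fanconi_anaemia	FANCM
fanconi_anaemia	PALB2
fanconi_anaemia	CHEK1
fanconi_anaemia	SLX4
fanconi_anaemia	FAN1
fanconi_anaemia	FAAP20
fanconi_anaemia	FAAP24
fanconi_anaemia	MUS81
fanconi_anaemia	EME1
non_homologous_end_joining	XRCC6
non_homologous_end_joining	XRCC5
non_homologous_end_joining	PRKDC
non_homologous_end_joining	LIG4
non_homologous_end_joining	XRCC4
non_homologous_end_joining	DCLRE1C
non_homologous_end_joining	NHEJ1
direct_damage_reversal	MGMT
direct_damage_reversal	ALKBH2
direct_damage_reversal	ALKBH3
other_genomic_stability	PAXIP1
other_genomic_stability	BLM
other_genomic_stability	MLL3
other_genomic_stability	CRIP1
other_genomic_stability	CDK12
other_genomic_stability	BAP1
other_genomic_stability	BARD1
other_genomic_stability	WRN
other_genomic_stability	BUB1
other_genomic_stability	CENPE
other_genomic_stability	ZW10
other_genomic_stability	TTK
other_genomic_stability	KNTC1
other_genomic_stability	AURKB
other_genomic_stability	POLB
other_genomic_stability	POLH
other_genomic_stability	POLQ
other_genomic_stability	TDP1
other_genomic_stability	TDP2
other_genomic_stability	NUDT1
other_genomic_stability	DUT
other_genomic_stability	RRM2B
other_genomic_stability	POLG
other_genomic_stability	REV3L
other_genomic_stability	MAD2L2
other_genomic_stability	REV1
other_genomic_stability	POLI
other_genomic_stability	POLK
other_genomic_stability	POLL
other_genomic_stability	POLM
other_genomic_stability	POLN
other_genomic_stability	TREX1
other_genomic_stability	TREX2
other_genomic_stability	APTX
other_genomic_stability	SPO11
other_genomic_stability	ENDOV
other_genomic_stability	UBE2A
other_genomic_stability	UBE2B
other_genomic_stability	RAD18
other_genomic_stability	SHPRH
other_genomic_stability	HLTF
other_genomic_stability	RNF168
other_genomic_stability	SPRTN
other_genomic_stability	RNF8
other_genomic_stability	RNF4
other_genomic_stability	UBE2V2
other_genomic_stability	UBE2N
other_genomic_stability	H2AFX
other_genomic_stability	CHAF1A
other_genomic_stability	SETMAR
other_genomic_stability	RECQL4
other_genomic_stability	MPLKIP
other_genomic_stability	DCLRE1A
other_genomic_stability	DCLRE1B
other_genomic_stability	PRPF19
other_genomic_stability	RECQL
other_genomic_stability	RECQL5
other_genomic_stability	HELQ
other_genomic_stability	RDM1
other_genomic_stability	NABP2
other_genomic_stability	ATRIP
other_genomic_stability	MDC1
other_genomic_stability	RAD1
other_genomic_stability	RAD9A
other_genomic_stability	HUS1
other_genomic_stability	RAD17
other_genomic_stability	TP53
other_genomic_stability	TP53BP1
other_genomic_stability	TOPBP1
other_genomic_stability	CLK2
other_genomic_stability	PER1
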