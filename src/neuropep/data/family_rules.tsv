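# Molluscan neuropeptide family rulebook
# name	kind	pattern	amidation_required	priority
FMRFamide	pattern	FMRF	1	10
luqin	c_terminal_motif	WRPQGRF	1	10
NPF	c_terminal_motif	GRPRF	1	10
CCK/SK	c_terminal_motif	GGGRF	1	10
myomodulin	c_terminal_motif	xxxMLRL	1	10
FxRIamide	c_terminal_motif	xSSFxRI	1	10
PGWamide	pattern	[ARTKS]PGW	1	10
allatostatin_B	trp_spacing	4,5	1	20
allatostatin_C	cys_spacing	6	1	20
buccalin	c_terminal_motif	GxL	1	30
RFamide	c_terminal_motif	RF	1	50
RYamide	c_terminal_motif	RY	1	50
Wamide	c_terminal_motif	W	1	60
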