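id	domain	order	lineage	variant_of	pattern	key_residues	note
M-I	mocf	1	.	.	G[TD]E!xxxG!xxx[DN]TxN!	2|E|adenosine contact (ADPr)|3KBQ:E11	wall of the molybdopterin pocket; beta1-alpha2; bolding of the leading G is typographically uncertain
M-II	mocf	2	.	.	VGD!NxxxH	2|D|catalytic/binding aspartate, only residue strict across all lineages|3KBQ:D44	between beta2 and alpha3; dimer interface
M-III	mocf	3	.	.	G!G!L!G!P!T!xD!D!xT	8|D|pyrophosphate binding|3KBQ:D75	GGTG-like motif; loop beta3-alpha4; largest fraction of the binding pocket
M-IV	mocf	4	.	.	Nx[KR]QA	2|KR|substrate-facing lysine/arginine|3KBQ:K114	weakly conserved outside the archaeal lineage
M-IV/1.3	mocf	4	1.3	M-IV	R!xK!M!A!xxP!	2|K|substrate-facing lysine|3KBQ:K114;3|M|substrate-facing methionine|3KBQ:M115	archaeal fingerprint form of M-IV
M-V	mocf	5	.	.	N!xxG!xA!PG!	.	beta6 to beta7; wall opposite M-I
M-VI	mocf	6	.	.	P!G![VP]P!xE![ML]	0|P|phosphate binding|3KBQ:P148;1|G|phosphate binding|3KBQ:G149	beta8-alpha7; PG pair shared with MogA/gephyrin
M-VII	mocf	7	.	.	PxL	.	short closing motif of the MocF domain
i-I	interdomain	1	.	.	GhGE!S	.	first interdomain block
i-I/1.3	interdomain	1	1.3	i-I	GhGE!SxhA!P!	.	archaeal form carries a conserved xhAP suffix
i-II	interdomain	2	.	.	EVxh[RK]h	.	second interdomain block; absent from the archaeal lineage
P-I	cina	1	.	.	A!E!S!CTGG!	2|S|NMN amide contact|2A9S:S31	beta1-alpha2; bottom of the active-site pocket
P-I/2.2.1.2	cina	1	2.2.1.2	P-I	E[QA][CG][ST][GA]G	.	inactive two-domain form; serine lost
P-I/2.2.3.4	cina	1	2.2.3.4	P-I	SEAACGG	.	fungal form; alanine at the S31-homologous offset
P-II	cina	2	.	.	G![AS]S	0|G|active-site wall glycine|2A9S:G46;2|S|active-site wall serine|2A9S:S48	contributed by the partner subunit of the dimer
P-II/2.2.2.2	cina	2	2.2.2.2	P-II	D!T!P!	.	inactive single-domain replacement of the G-A/S-S wall
P-II/2.2.1.2	cina	2	2.2.1.2	P-II	A![DP][EQ]	.	inactive two-domain replacement
P-III	cina	3	.	.	Y!xNxxK!	0|Y|catalytic tyrosine|2A9S:Y58;2|N|amide-positioning asparagine|2A9S:N60;5|K|catalytic lysine|2A9S:K63	beta2-alpha3; broad active-site surface
P-III/2.2.2.2	cina	3	2.2.2.2	P-III	F!xD!xxK!	.	documented Y58F plus N60D double point mutation of the canonical block
P-III/2.2.3.4	cina	3	2.2.3.4	P-III	YS[ML]K[TQ]R	0|Y|tyrosine retained|2A9S:Y58	fungal form keeps the tyrosine, loses the lysine at its canonical offset
P-IV	cina	4	.	.	G![AV]VS	.	alpha4-alpha5; outer rim of the surface depression
P-IV/2.2.2.2	cina	4	2.2.2.2	P-IV	[ST]AVS	.	inactive single-domain form
P-IV/2.2.1.2	cina	4	2.2.1.2	P-IV	[GE]x[VL][SA]	.	inactive two-domain form
P-IV/2.2.3.4	cina	4	2.2.3.4	P-IV	MGPS	.	fungal form
P-V	cina	5	.	.	M!AxG!x	.	structural block away from the active site; deleted in inactive two-domain enzymes
P-VI	cina	6	.	.	[ST]G[IV]A!G!P!xG!G!	0|ST|NMN amino-group contact|2A9S:S105;1|G|NMN amino-group contact|2A9S:G106	beta3-beta4; most conserved CinA block
P-VI/2.2.1.2	cina	6	2.2.1.2	P-VI	[SV]xxxxx[EH]	.	degraded inactive two-domain form
P-VI/2.2.2.2	cina	6	2.2.2.2	P-VI	[ST]GYGGP	.	inactive single-domain form
P-VII	cina	7	.	.	KPVG!TV	3|G|strictly conserved glycine near the pocket|2A9S:G120	near P-IV; whole block deleted in inactive two-domain enzymes
P-VIII	cina	8	.	.	Rxx[VI]R	0|R|phosphate-binding arginine|2A9S:R145	last alpha-helix; closes the active-site pocket
P-IX	cina	9	.	.	L!xxL!xxxL!	.	leucine zipper-like fingerprint on the long curved final helix
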