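motif_id	name	motif_class	effector	n_sites	distribution_group
RF00059	TPP	riboswitch	thiamin pyrophosphate	564	A
RF00174	Cobalamin	riboswitch	adenosylcobalamin	536	A
RF00504	Glycine	riboswitch	glycine	324	A
RF00080	yybP-ykoY	riboswitch	unknown	232	A
RF00050	FMN	riboswitch	flavin mononucleotide	233	A
RF00162	SAM	riboswitch	S-adenosylmethionine	257	B
RF00515	PyrR	pyrR	unknown	211	B
RF00168	Lysine	riboswitch	lysine	186	B
RF00167	Purine	riboswitch	guanine, adenine	141	B
RF01051	GEMM	riboswitch	cyclic di-GMP	89	B
RF00522	PreQ1	riboswitch	pre-queuosine-1	72	B
RF01055	MOCO	riboswitch	molybdenum cofactor	62	B
RF00379	ydaO-yuaA	riboswitch	ATP	59	B
RF00442	ykkC-yxkD	riboswitch	unknown	58	B
RF01068	mini-ykkC	riboswitch	unknown	67	B
RF00380	ykoK	riboswitch	magnesium	48	B
RF00234	glmS	riboswitch	glucosamine-6-phosphate	44	B
RF01057	SAH	riboswitch	S-adenosylhomocysteine	27	B
RF00521	SAM-Alpha	riboswitch	S-adenosylmethionine	39	C
RF00517	serC	riboswitch	unknown	32	C
RF01831	THF	riboswitch	tetrahydrofolate	23	C
RF01054	PreQ1-II	riboswitch	pre-queuosine-1	17	C
RF01070	sucA	riboswitch	unknown	14	C
RF01739	glnA	riboswitch	glutamine	13	C
RF00634	SAM-IV	riboswitch	S-adenosylmethionine	13	C
RF01727	SAM-SAH	riboswitch	S-adenosylmethionine, S-adenosylhomocysteine	13	C
RF01767	Smk-box	riboswitch	S-adenosylmethionine	13	C
RF00518	speF	riboswitch	unknown	12	C
RF01724	SAM-Chlorobi	riboswitch	S-adenosylmethionine	11	C
RF00516	ylbH	riboswitch	unknown	10	C
RF00520	ybhL	riboswitch	unknown	8	C
RF01056	Mg sensor	riboswitch	magnesium	5	C
RF00557	L10 leader	ribosomal_leader	unknown	108	D
RF00114	S15 leader	ribosomal_leader	unknown	98	D
RF00558	L20 leader	ribosomal_leader	unknown	75	D
RF00559	L21 leader	ribosomal_leader	unknown	67	D
RF00556	L19 leader	ribosomal_leader	unknown	61	D
RF00555	L13 leader	ribosomal_leader	unknown	43	D
RF00514	His leader	aa_leader	unknown	49	E
RF00513	Trp leader	aa_leader	unknown	48	E
RF00506	Thr leader	aa_leader	unknown	45	E
RF00512	Leu leader	aa_leader	unknown	43	E
RF00230	T-box	tbox	unknown	1134	F
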