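substrate	position	hydroxylase	deaminase	deaminase_variant	decarboxylase	reductase	product
val	C4	MFL	AAD	oxidative	KDC	YqhD	MPO
leu	C4	MFL	AAD	oxidative	KDC	YqhD	IPDO
nva	C4	MFL	AAD	oxidative	KDC	YqhD	1,3-BDO
nle	C4	MFL	AAD	oxidative	KDC	YqhD	1,3-PTD
ile	C4_1	HilA	AAD	oxidative	KDC	YqhD	2-E-1,3-PDO
ile	C4_2	HilB	AAD	oxidative	KDC	YqhD	2-M-1,3-BDO
leu	C5	GriE	AAD	oxidative	KDC	YqhD	2-M-1,4-BDO
nva	C5	GriE	AAD	oxidative	KDC	YqhD	1,4-BDO
nle	C5	GriE	AAD	oxidative	KDC	YqhD	1,4-PTD
thr	C4	BPE	IlvA	dehydrating	KDC	YqhD	1,3-PDO
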