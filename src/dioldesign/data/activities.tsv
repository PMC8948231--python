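enzyme_id	substrate_id	status	source_anchor
MFL	leu	active	hydroxylation of leucine at C-4 (natural substrate; strain DL01 produced IPDO from leucine)
MFL	kic	active	MFL showed activity on KIC (enzyme assay; route R3 verified with strain DL01-R34)
MFL	ipt	inactive	missing hydroxylation activity of MFL towards isopentanol (strain DL01-R4 produced no IPDO)
MFL	thr	inactive	MFL is inactive towards threonine
AAD	leu	active	AAD deaminates leucine to KIC (strain DL01 route)
AAD	4ohleu	active	strain DL01-R12 produced 374.1 mg/L IPDO from 4OH-Leu via AAD/KDC/YqhD
KDC	leu	inactive	KDC had no activity on leucine (enzyme assay)
KDC	4ohleu	inactive	without AAD, KDC and YqhD had no catalytic activity on 4OH-Leu
KDC	kic	active	Ehrlich decarboxylation of KIC; isopentanol formed when fed KIC-derived intermediates
KDC	4ohkic	active	DL01-R12 converted 4OH-Leu to IPDO once deaminated, so KDC acts on 4OH-KIC
YqhD	leu	inactive	YqhD had no activity on leucine (enzyme assay)
YqhD	4ohleu	inactive	without AAD, KDC and YqhD had no catalytic activity on 4OH-Leu
YqhD	mbal	active	Ehrlich reduction of 3-methylbutanal to isopentanol (route R4 precursor feeding)
YqhD	hmbald	active	YqhD reduces 3-hydroxy-3-methylbutanal to IPDO (final step of R1/R3)
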