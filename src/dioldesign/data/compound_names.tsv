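id	abbr	name	structure
val	Val	L-valine	C3;COOH@1;NH3@2;BR@3:1;BR@3:1
leu	Leu	L-leucine	C5;COOH@1;NH3@2;BR@4:1
ile	Ile	L-isoleucine	C5;COOH@1;NH3@2;BR@3:1
nva	Nva	L-norvaline	C5;COOH@1;NH3@2
nle	Nle	L-norleucine	C6;COOH@1;NH3@2
thr	Thr	L-threonine	C4;COOH@1;NH3@2;OH@3
mpo	MPO	2-methyl-1,3-propanediol	C3;OH@1;OH@3;BR@2:1
ipdo	IPDO	isopentyldiol (3-methyl-1,3-butanediol)	C4;OH@1;OH@3;BR@3:1
13bdo	1,3-BDO	1,3-butanediol	C4;OH@1;OH@3
13ptd	1,3-PTD	1,3-pentanediol	C5;OH@1;OH@3
2e13pdo	2-E-1,3-PDO	2-ethyl-1,3-propanediol	C3;OH@1;OH@3;BR@2:2
2m13bdo	2-M-1,3-BDO	2-methyl-1,3-butanediol	C4;OH@1;OH@3;BR@2:1
2m14bdo	2-M-1,4-BDO	2-methyl-1,4-butanediol	C4;OH@1;OH@4;BR@2:1
14bdo	1,4-BDO	1,4-butanediol	C4;OH@1;OH@4
14ptd	1,4-PTD	1,4-pentanediol	C5;OH@1;OH@4
13pdo	1,3-PDO	1,3-propanediol	C3;OH@1;OH@3
4ohleu	4OH-Leu	4-hydroxy-leucine	C5;COOH@1;NH3@2;OH@4;BR@4:1
kic	KIC	2-ketoisocaproate	C5;COOH@1;OXO@2;BR@4:1
4ohkic	4OH-KIC	4-hydroxy-4-methyl-2-oxopentanoate	C5;COOH@1;OXO@2;OH@4;BR@4:1
hmbald	HMB-al	3-hydroxy-3-methylbutanal	C4;OXO@1;OH@3;BR@3:1
mbal	3MB-al	3-methylbutanal	C4;OXO@1;BR@3:1
ipt	IPT	isopentanol (3-methylbutan-1-ol)	C4;OH@1;BR@3:1
4ohthr	4OH-Thr	4-hydroxy-threonine	C4;COOH@1;NH3@2;OH@3;OH@4
ohkb	4OH-KB	2-oxo-4-hydroxybutanoate	C4;COOH@1;OXO@2;OH@4
3hpald	3HP-al	3-hydroxypropanal	C3;OXO@1;OH@3
sucsal	SSA	succinate semialdehyde	C4;COOH@1;OXO@4
4hb	4HB	4-hydroxybutyrate	C4;COOH@1;OH@4
4hba	4HB-al	4-hydroxybutanal	C4;OXO@1;OH@4
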