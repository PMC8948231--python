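# Transformed standard Gibbs energies of formation (kJ/mol) at 298.15 K,
# pH 7.0, ionic strength 0.25 M, 1 M reference concentrations.
# Group contributions for sp3 carbon backbones were solved from aqueous
# standard formation energies of small reference solutes (methanol,
# ethanol, 1-propanol, acetaldehyde, acetate, pyruvate, L-alanine,
# L-lactate, glycerol) Legendre-transformed to pH 7
# (dGf' = dGf(aq) + N_H * RT ln(10) * pH = dGf(aq) + N_H * 39.96 kJ/mol).
# Overrides for cofactors and anchored metabolites come from standard
# biochemical compilations and redox potentials (NAD(P)+/NAD(P)H -320 mV,
# O2/H2O +816 mV; ATP hydrolysis -32 kJ/mol).  The nicotinamide and
# adenosine scales are internally anchored (nad = nadp = adp = pi = coa =
# 0); only differences within each conserved moiety pair are meaningful,
# which is all any balanced reaction uses.
# The single nonadditive correction is a 1,3-hydroxy/carbonyl
# intramolecular hydrogen bond (beta-hydroxy ketone/aldehyde motif),
# applied once per hydroxyl/oxo pair on carbons at topological distance 2.
kind	id	value_kj_mol
meta	version	1.0.0
origin	origin	0.0
group	C_H3	108.85
group	C_H2	85.70
group	C_H1	68.85
group	C_H0	51.70
group	carboxylate	-358.25
group	amino	88.95
group	hydroxyl	-136.35
group	oxo	-156.90
correction	hydroxy_carbonyl_1_3	-7.00
override	h2o	-157.60
override	h	0.00
override	o2	16.40
override	co2	-386.00
override	nh4	80.50
override	akg	-633.60
override	succ	-530.60
override	nad	0.00
override	nadh	53.40
override	nadp	0.00
override	nadph	53.40
override	atp	189.60
override	adp	0.00
override	pi	0.00
override	coa	0.00
override	ac	-249.40
override	accoa	-60.30
override	succoa	-341.00
override	glc	-426.70
override	glu	-377.80
override	pyr	-352.40
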