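# Methods

## Chemistry data model

Pathway molecules (C3–C6 amino acids, hydroxy amino acids, 2-keto acids,
aldehydes, diols/triols) are represented as acyclic carbon trees with
per-carbon substituent multisets drawn from {carboxyl, amino, hydroxyl,
oxo}; hydrogens are implicit from valence.  C1 is the carboxyl carbon
(amino-acid numbering), and the carboxyl group is a substituent *on* its
carbon.  This deliberately excludes aromatics, rings and stereochemistry:
the cascade transforms only ever create or consume the four substituent
types on sp³ backbones, and molecule identity within this chemotype space
is decided by an AHU canonical encoding of the labelled free tree (rooted
at its graph center), which is invariant under renumbering and
branch-enumeration order.

All species are written as their pH-7 majority forms: carboxylates
deprotonated, amines as ammonium, free "ammonia" carried as NH₄⁺, with
explicit H⁺ where charge balance requires it.  Under this convention all
four cascade reactions balance exactly in every element and in charge —
the oxidative deamination, for example, is
`AA + ½O₂ → keto-acid⁻ + NH₄⁺` with no water term (the conventionally
printed form with NH₃ is kept as a display alias).  The dehydrating
IlvA-type deamination likewise balances as
`β-OH-AA → keto-acid⁻ + NH₄⁺` with no net water: the dehydration and the
subsequent enamine hydrolysis cancel.  Stoichiometric coefficients are
exact rationals so that ½O₂ never incurs floating-point drift; every
reaction emitted anywhere in the package is asserted to have zero element
and charge residuals.

The oxidative deaminase is modelled with ½O₂ consumption and no NADH, the
membrane-oxidase electron fate being out of scope; whether the in-vivo
electron acceptor chain regenerates additional reducing power is a known
simplification.  The keto acid of the IPDO route is named
4-hydroxy-4-methyl-2-oxopentanoate; the historical label
"4-hydroxy-4-methylglutaric acid" sometimes attached to this intermediate
does not mass-balance a C6 cascade and is treated as an alias of the
same species.

Isoleucine's two γ positions are addressed as C4¹ (the 3-methyl branch
carbon, hydroxylated by HilA, leading to 2-ethyl-1,3-propanediol) and C4²
(the main-chain C4, HilB, leading to 2-methyl-1,3-butanediol).  The β
(C3) position is representable on every substrate but ships with no
configured enzyme; requesting it warns rather than fails, since no
β-specific hydroxylase is part of the shipped table.

## Cascade builder and reaction orders

`build_cascade` always emits the platform order hydroxylation →
deamination → decarboxylation → reduction; for threonine the dehydrating
deaminase replaces the oxidative one (hydroxylation must precede it, as
the native deaminase otherwise consumes the substrate).  Alternative
reaction orders are handled by the route-analysis layer: with
decarboxylation+reduction lumped (reduction always follows
decarboxylation), the 3! = 6 orderings R1–R6 are each replayed through
the skeleton transforms.  Replay tracks carbon identity, not IUPAC
numbers, so "the C4 position of leucine" remains addressable after
decarboxylation renumbers the backbone (it becomes C3 of isopentanol in
route R4).  A step whose chemical precondition fails — decarboxylation
without the 2-oxo-acid motif, hydroxylation of a substituted carbon — is
recorded as chemically impossible; this verdict comes from the transforms
alone, never from the activity matrix.

Activity facts are a three-valued map (active / inactive / unknown) over
(enzyme, canonical substrate key), shipped as a TSV with a source anchor
per fact.  Unknown is first-class because only some pairs were ever
assayed; the default strict policy counts unknown as infeasible, the
permissive policy as feasible.  Under the shipped facts the strict filter
retains exactly R1 and R3 and reports each eliminated route's failing
step (R2: DR on 4-hydroxy-leucine; R4: hydroxylation of isopentanol;
R5/R6: DR on leucine).  Note that R4 is chemically replayable and even
thermodynamically attractive — it fails purely on the hydroxylase's lack
of activity towards isopentanol, a good illustration of why kinetic
feasibility and thermodynamic ranking are kept separate.  No quantitative
flux split between coexisting feasible routes is attempted.

## Thermodynamic parameterisation

Transformed formation energies ΔfG′° are additive over a small group set
(backbone units CH₃/CH₂/CH/C by implicit hydrogen count; carboxylate,
which absorbs its carbon; amino; hydroxyl; oxo) plus per-compound
overrides for cofactors and anchored metabolites.  The shipped table
(v1.0.0, kJ/mol, 298.15 K, pH 7.0, I = 0.25 M) was derived once as
follows and then frozen:

* group values solved from aqueous standard formation energies of small
  reference solutes (methanol, ethanol, 1-propanol, acetaldehyde,
  acetate, pyruvate, L-alanine, L-lactate, glycerol), Legendre-transformed
  to pH 7 via ΔfG′° = ΔfG°(aq) + N_H·RT·ln10·pH;
* overrides from standard biochemical compilations and redox anchors:
  NAD(P)⁺/NAD(P)H at −320 mV, O₂/H₂O at +816 mV (equivalently
  NAD(P)H + ½O₂ → NAD(P)⁺ + H₂O at −219 kJ/mol), ATP hydrolysis at
  −32 kJ/mol.  Moiety scales (nicotinamide, adenosine, CoA) are anchored
  internally (e.g. ΔfG′°(NADP⁺) := 0); only within-moiety differences are
  meaningful, which is all a balanced reaction ever uses.

The derivation yields, as consistency checks against classic
biochemistry: sp³ C–H hydroxylation by ½O₂ ≈ −154 to −160 kJ/mol,
oxidative deamination ≈ −191 kJ/mol, 2-keto acid decarboxylation
≈ −11 kJ/mol, NADPH aldehyde reduction ≈ −16 kJ/mol — reproducing the
qualitative ordering hydroxylation ≫ deamination > decarboxylation >
reduction.

One nonadditive correction is carried: a −7 kJ/mol stabilisation for a
hydroxyl and a carbonyl on carbons at topological distance 2 (the
β-hydroxy ketone/aldehyde motif, e.g. 4-hydroxy-KIC and
3-hydroxy-3-methylbutanal), representing the intramolecular six-membered
hydrogen bond such compounds form; the magnitude is a typical
intramolecular H-bond strength.  Physically this is why the per-step
profile is not a pure permutation across reaction orders: the route that
*creates* the stabilised intermediate in its deamination step (R1)
spreads its driving force slightly more evenly than the route that
creates it in the hydroxylation step (R3).  Pure additivity would make
the R1 and R3 step multisets identical.

Conditions: Δ<sub>r</sub>G′ = Σν·ΔfG′° + RT·Σν·ln c, defaulting to 1 mM
for every solute including dissolved O₂ and CO₂ (the ΔG′m convention);
H⁺ and H₂O never enter the concentration term (activities fixed by pH
and solvent).  A partial-pressure gas convention is available by setting
explicit concentrations.  The table's pH/ionic strength are declared on
the conditions object for traceability and must match the table version;
no Legendre re-transformation to other pH values is implemented.

Profile summaries: bottleneck = max step Δ<sub>r</sub>G′; harmony =
population standard deviation of the step values, our formalisation of
the "ideal profile" in which all steps share one driving force
(harmony = 0).  Ranking is (bottleneck ascending, harmony ascending).
Endpoint identity across orderings is asserted to 1e-6 kJ/mol — but only
over chemically replayable orderings: R2/R5/R6 contain undefined
transforms (DR without a keto acid) and therefore have no profile at
all.  The plotted y-values of the original figures are not tabulated
anywhere and are not reproduction targets; the package asserts the
qualitative profile shape, the Hess identities and the ≤ −100 kcal/mol
hydroxylation bound instead.

## Flux balance analysis

The LP maximises the target exchange flux subject to S·v = 0 and bounds,
with glucose uptake *fixed* (both bounds) at 15 mmol·gDCW⁻¹·h⁻¹ — the
stated uptake is read in the standard FBA unit, the time unit being
implied.  O₂, N, P and S sources are unconstrained.  Added IPDO reactions
are irreversible, IPDO export is a free exchange; biomass is not forced
and non-growth-associated ATP maintenance defaults to 0, both being
exposed as knobs because yield can be sensitive to them and neither
setting is externally fixed — the package reports the effect rather than
hiding it.  An audit mode installs the four pathway reactions exactly as
conventionally printed (without explicit H⁺), flagged unbalanced on
purpose.

BiGG JSON and SBML-FBC parsing is delegated to cobrapy behind the
`read_model` surface; the native JSON format round-trips exactly.  The
LP is solved with scipy's HiGHS; tests cross-check the optimum against
cobrapy/GLPK and, on the core fixture, against an exact
rational-arithmetic two-phase simplex, and assert invariance under
reaction permutation, the 6/5 carbon bound for IPDO on glucose, and
relaxation monotonicity.

## The synthetic core model

The core network is hand-curated, programmatically generated data — not
random — because the FBA properties need a known-good backbone.  It lumps
glycolysis (glucose → 2 pyruvate + 2 ATP + 2 NADH), PDH, the full TCA
cycle (succinate dehydrogenase lumped to ½O₂ without energy recovery),
anaplerotic carboxylation, NADPH-linked glutamate dehydrogenase, the
acetolactate route to 2-ketoisocaproate and leucine
(AlsS/IlvCD/LeuABCD/IlvE, mirroring the engineered precursor-supply
strains), oxidative phosphorylation at P/O = 2, a reversible
transhydrogenase, an optional oxidative-PPP NADPH source, ATP maintenance
and exchanges (glucose, O₂, NH₄⁺, Pᵢ, SO₄²⁻, CO₂, H₂O, H⁺, leucine
secretion).  Every internal reaction is element- and charge-balanced.

With the IPDO pathway added and glucose fixed at 15, the core model's
maximum yield is exactly ½ mol IPDO/mol glucose (verified against the
exact simplex).  This is deliberately a conservative, small (~30-reaction)
network: it cannot reproduce the genome-scale optimum of the full
*E. coli* reconstruction, whose richer redox and carbon routing gives a
higher value, and it does not emulate regulation, kinetics, by-product
spectra or growth — so passing tests demonstrate correctness of the
machinery, not quantitative predictions for real strains.  The
genome-scale check itself runs whenever `models/iY75_1357.json` is
present locally; the model is not bundled.

What the generators do not emulate more broadly: enzyme kinetics and
expression, intermediate toxicity, fermentation time courses and titers.
Randomness (activity matrices, thermo-table noise) is always seeded and
bit-reproducible; σ = 2 kJ/mol group noise across 100 seeds never flips
the hydroxylation sign, the step being two orders of magnitude larger
than the perturbation.

## Problem sizes and numerical choices

All shipped computations are desk-scale: 10 cascades, 6 orderings, a
~30-reaction LP; the exact-simplex oracle (Bland's rule, Fractions) runs
on the fixture in well under a second.  Route-filter equivalence is
checked against a brute-force checker on 200 seeded random matrices.
Hess tolerances are 1e-6 kJ/mol (profile sums are plain floating-point
additions of ~4 terms); LP comparisons use 1e-6 relative; canonical-key
congruence and ledger additivity are exercised property-style with
derandomised generators.  Ties in route ranking (equal bottlenecks) are
broken by harmony, then input order.
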