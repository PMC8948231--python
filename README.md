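# dioldesign

A design toolkit for biosynthesising C3–C5 diols from amino acids by
combining one **oxidative** and one **reductive** hydroxyl-group
formation.  It is aimed at metabolic engineers evaluating the platform
pathway

> amino acid → hydroxy amino acid → hydroxy 2-keto acid → hydroxy
> aldehyde → diol

catalysed consecutively by an Fe(II)/α-ketoglutarate-dependent amino-acid
hydroxylase, an L-amino acid deaminase, an α-keto acid decarboxylase and
an NADPH-dependent aldehyde reductase.  One hydroxyl is installed
oxidatively (C–H + α-KG + O₂ → C–OH + succinate + CO₂, strongly
exergonic, no NAD(P)H cost); the other comes from the former carboxyl
neighbourhood through an Ehrlich-type deamination / decarboxylation /
reduction tail.  Against the classical all-reductive routes (e.g.
succinate → 1,4-butanediol: 1 ATP + 4 NAD(P)H), the combined route needs
only **1 NADPH and no ATP** per diol.

The package covers, as importable modules and a CLI:

| module | what it does |
| --- | --- |
| `dioldesign.chem` | carbon-skeleton data model, exact-rational reactions, element/charge balance, net cofactor ledgers, canonical molecule keys |
| `dioldesign.cascade` | the four cascade transforms, pathway construction, the ten-diol substrate × hydroxylation-position table |
| `dioldesign.routes` | the six reaction orders (R1–R6) of the lumped three-step cascade, replay of intermediates, feasibility filtering against a three-valued enzyme–substrate activity matrix |
| `dioldesign.thermo` | group-contribution ΔfG′°, per-step Δ<sub>r</sub>G′ profiles, bottleneck and harmony scores, route ranking |
| `dioldesign.fba` | stoichiometric models (native JSON / BiGG JSON / SBML-FBC), the four-reaction IPDO pathway extension, LP maximum theoretical yield |
| `dioldesign.synthetic` | a balanced core *E. coli* model, random activity matrices, perturbed thermo tables |
| `dioldesign.cli` | `dioldesign design / routes / thermo / ledger / fba` |

## The quantities it computes

For a route with per-step transformed reaction energies
Δ<sub>r</sub>G′₁ … Δ<sub>r</sub>G′ₙ (group-contribution estimate, 298.15 K,
pH 7, ionic strength 0.25 M, 1 mM metabolites):

* **bottleneck** = max<sub>i</sub> Δ<sub>r</sub>G′ᵢ — the least-driven step;
* **harmony** = population standard deviation of the Δ<sub>r</sub>G′ᵢ —
  0 for the ideal profile in which every step carries the same driving
  force;
* **endpoint** = ΣΔ<sub>r</sub>G′ᵢ, identical for every ordering of the
  same overall conversion (Hess's law; asserted to 10⁻⁶ kJ/mol).

Maximum theoretical yield is the LP optimum
max v<sub>product</sub> s.t. S·v = 0, bounds, glucose uptake fixed at
15 mmol·gDCW⁻¹·h⁻¹, divided by the uptake (mol/mol).

## Worked example

```bash
dioldesign --outdir out design    # the ten-diol product table
dioldesign --outdir out thermo    # R1 vs R3 thermodynamic profiles
dioldesign --outdir out ledger    # cofactor ledger of the IPDO cascade
dioldesign --outdir out fba --add-ipdo   # yield on the core model
```

`out/thermo.tsv` (leucine → isopentyldiol, IPDO):

```
## route R1
step  reaction_ids     drG_kJ    drG_kcal  cumulative_kJ
H     R1_1_H           -452.900  -108.246  -452.900
D     R1_2_D           -206.262  -49.298   -659.162
DR    R1_3_Dc+R1_3_R   -36.724   -8.777    -695.886
## route R3
step  reaction_ids     drG_kJ    drG_kcal  cumulative_kJ
D     R3_1_D           -199.262  -47.625   -199.262
H     R3_2_H           -459.900  -109.919  -659.162
DR    R3_3_Dc+R3_3_R   -36.724   -8.777    -695.886
```

Reading it: the α-KG-coupled hydroxylation contributes about
−108 kcal/mol of driving force; both orders end at the same cumulative
−695.9 kJ/mol (Hess), but R1 (hydroxylation first) starts with the
stronger push and its steps decrease gradually — it is the more
harmonised profile (σ = 170.9 vs 174.3 kJ/mol) and ranks first.  The
`ledger` report shows the whole cascade consumes 1 NADPH and 0 ATP per
IPDO (with 1 α-KG recycled to succinate), and `fba --add-ipdo` prints a
maximum theoretical yield of 0.5000 mol IPDO/mol glucose on the built-in
core network (the genome-scale model gives a higher value because it can
route carbon and redox more flexibly).

`routes` reproduces the reaction-order analysis: six orderings, of which
only R1 (H→D→DR) and R3 (D→H→DR) survive the transcribed activity
matrix — R2 dies at the decarboxylase/reductase step on 4-hydroxy-leucine,
R4 at hydroxylation of isopentanol, R5/R6 at decarboxylation of leucine
itself.

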