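"""Four-step cascade construction: amino acid -> diol.

The platform pathway converts an alpha-amino acid into a 1,n-diol with one
carbon fewer through four consecutive enzymatic steps:

1. hydroxylation (Fe(II)/alpha-KG dioxygenase): a C-H bond at the beta,
   gamma or delta position is hydroxylated while alpha-ketoglutarate is
   oxidised to succinate + CO2 with O2,
2. deamination (L-amino acid deaminase, or the dehydrating IlvA-type
   threonine deaminase which also removes the native beta-OH),
3. decarboxylation (alpha-keto acid decarboxylase, C1 leaves as CO2),
4. reduction (NADPH-dependent aldehyde reductase).

One hydroxyl of the product is formed oxidatively in step 1; the other is
formed reductively from the former carboxyl carbon neighbourhood in steps
2-4 (an Ehrlich-type sequence).  This module builds the skeleton
transforms, the balanced reactions and the complete pathways, and derives
the product diol set for the shipped substrate x hydroxylation-position
configuration.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .chem import (CarbonSkeleton, ChemError, Compound, Reaction,
                   cofactor_compounds)


class CascadeError(ChemError):
    pass


class PositionError(CascadeError):
    """Requested hydroxylation position does not exist / cannot accept OH."""


class SubstrateError(CascadeError):
    """Substrate lacks the chemical motif a transform requires."""


# ---------------------------------------------------------------------------
# structure mini-language and the named-compound registry


def skeleton_from_structure(text: str) -> CarbonSkeleton:
    """Build a skeleton from a compact structure string.

    Format: ``"C5;COOH@1;NH3@2;OH@4;BR@4:1"`` -- a main chain of five
    carbons, carboxyl at C1, ammonium at C2, hydroxyl at C4 and a
    one-carbon branch at C4.  ``BR@p:n`` attaches a linear n-carbon branch
    at main-chain position p and may repeat (geminal branches).
    """
    parts = [p.strip() for p in text.split(";") if p.strip()]
    if not parts or not parts[0].startswith("C"):
        raise CascadeError(f"structure must start with chain length: {text!r}")
    n = int(parts[0][1:])
    subs_for = {"COOH": "carboxyl", "NH3": "amino", "OH": "hydroxyl",
                "OXO": "oxo"}
    chain_subs: Dict[int, List[str]] = {}
    branches: List[Tuple[int, int]] = []
    for token in parts[1:]:
        head, _, loc = token.partition("@")
        if head == "BR":
            pos, _, ln = loc.partition(":")
            branches.append((int(pos), int(ln or 1)))
        elif head in subs_for:
            chain_subs.setdefault(int(loc), []).append(subs_for[head])
        else:
            raise CascadeError(f"unknown structure token {token!r}")
    sk, uids = CarbonSkeleton.chain(n, chain_subs)
    for pos, ln in branches:
        sk.add_branch(uids[pos - 1], ln)
    sk.validate()
    return sk


@dataclass
class NamedCompound:
    id: str
    abbr: str
    name: str
    structure: str


def _load_name_table() -> List[NamedCompound]:
    text = resources.files("dioldesign.data").joinpath(
        "compound_names.tsv").read_text()
    return [NamedCompound(r["id"], r["abbr"], r["name"], r["structure"])
            for r in csv.DictReader(io.StringIO(text), delimiter="\t")]


class CompoundRegistry:
    """Compound lookup keyed by id and by canonical skeleton key.

    Seeded with the cofactor set and the shipped named compounds (the six
    substrate amino acids, the ten product diols and the characterised
    intermediates).  Skeletons produced by cascade transforms that match a
    named compound get its id/name; unknown skeletons get generated ids and
    systematic placeholder names.
    """

    def __init__(self) -> None:
        self.compounds: Dict[str, Compound] = dict(cofactor_compounds())
        self.abbreviations: Dict[str, str] = {}
        self._by_key: Dict[str, str] = {}
        self._counter = 0
        for row in _load_name_table():
            sk = skeleton_from_structure(row.structure)
            cpd = Compound.from_skeleton(row.id, row.name, sk)
            self._register(cpd)
            self.abbreviations[row.id] = row.abbr

    def _register(self, cpd: Compound) -> None:
        if cpd.id in self.compounds:
            raise CascadeError(f"duplicate compound id {cpd.id}")
        self.compounds[cpd.id] = cpd
        if cpd.key:
            self._by_key[cpd.key] = cpd.id

    def __getitem__(self, cid: str) -> Compound:
        return self.compounds[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.compounds

    def by_key(self, key: str) -> Optional[Compound]:
        cid = self._by_key.get(key)
        return self.compounds[cid] if cid else None

    def get_or_create(self, skeleton: CarbonSkeleton) -> Compound:
        key = skeleton.canonical_key()
        existing = self.by_key(key)
        if existing is not None:
            return existing
        self._counter += 1
        formula = skeleton.formula()
        fstr = "".join(f"{e}{formula[e]}"
                       for e in ("C", "H", "N", "O") if e in formula)
        cpd = Compound.from_skeleton(
            f"cpd{self._counter:03d}", f"unnamed {fstr} compound", skeleton)
        self._register(cpd)
        return cpd

    def abbr_for_key(self, key: str) -> Optional[str]:
        cid = self._by_key.get(key)
        return self.abbreviations.get(cid) if cid else None


#: hydroxylatable positions per substrate, as chain/branch coordinates in
#: the structure strings above.  C1 is the carboxyl carbon (amino-acid
#: numbering).  Isoleucine's two gamma positions: C4_1 is the 3-methyl
#: branch carbon (HilA; leads to 2-E-1,3-PDO) and C4_2 the main-chain C4
#: (HilB; leads to 2-M-1,3-BDO).  C3 (beta) is addressable on every
#: substrate but no shipped enzyme is configured for it.
_POSITION_PATHS: Dict[str, Dict[str, Tuple[str, int]]] = {
    # token -> ("chain", 1-based position) or ("branch", index of branch carbon)
    "val": {"C3": ("chain", 3), "C4": ("branch", 1)},
    "leu": {"C3": ("chain", 3), "C4": ("chain", 4), "C5": ("chain", 5)},
    "ile": {"C3": ("chain", 3), "C4_1": ("branch", 1),
            "C4_2": ("chain", 4), "C5": ("chain", 5)},
    "nva": {"C3": ("chain", 3), "C4": ("chain", 4), "C5": ("chain", 5)},
    "nle": {"C3": ("chain", 3), "C4": ("chain", 4), "C5": ("chain", 5)},
    "thr": {"C4": ("chain", 4)},
}

POSITION_ALIASES = {"C4¹": "C4_1", "C4²": "C4_2", "C4^1": "C4_1",
                    "C4^2": "C4_2"}

SUBSTRATE_IDS = tuple(_POSITION_PATHS)


def substrate_position_uid(registry: CompoundRegistry, substrate_id: str,
                           position: str) -> int:
    """Resolve a position token (e.g. ``"C4"``) to the carbon uid on the
    registry's substrate skeleton."""
    position = POSITION_ALIASES.get(position, position)
    try:
        kind, idx = _POSITION_PATHS[substrate_id][position]
    except KeyError:
        known = sorted(_POSITION_PATHS.get(substrate_id, {}))
        raise PositionError(
            f"substrate {substrate_id!r} has no position {position!r} "
            f"(known: {known})") from None
    sk = registry[substrate_id].skeleton
    assert sk is not None
    # chain carbons were added first, in order; branch carbons after
    carbons = sk.carbons()
    if kind == "chain":
        return carbons[idx - 1]
    # branch carbons: uids after the main chain, in branch-addition order
    chain_len = _chain_length(registry[substrate_id])
    return carbons[chain_len + idx - 1]


def _chain_length(cpd: Compound) -> int:
    # main-chain length as declared in the structure table
    for row in _load_name_table():
        if row.id == cpd.id:
            return int(row.structure.split(";")[0][1:])
    raise CascadeError(f"{cpd.id} is not a shipped named compound")


# ---------------------------------------------------------------------------
# skeleton transforms


def apply_hydroxylation(skeleton: CarbonSkeleton, uid: int) -> CarbonSkeleton:
    """Add a hydroxyl at carbon ``uid`` (oxidative C-H hydroxylation).

    The position must exist, carry at least one H and must not already
    bear a hydroxyl, oxo or carboxyl group.
    """
    new = skeleton.copy()
    try:
        subs = new.substituents(uid)
        if new.implicit_h(uid) < 1:
            raise PositionError(f"carbon {uid} has no C-H bond to oxidise")
        if subs["hydroxyl"] or subs["oxo"] or subs["carboxyl"]:
            raise PositionError(f"carbon {uid} is already substituted")
    except ChemError as exc:
        raise PositionError(str(exc)) from None
    new.add_substituent(uid, "hydroxyl")
    return new


def _alpha_carbon(skeleton: CarbonSkeleton) -> Tuple[int, int]:
    """(carboxyl carbon uid, alpha carbon uid) of a 2-amino acid."""
    for uid in skeleton.carbons():
        if skeleton.substituents(uid)["carboxyl"]:
            for nb in skeleton.neighbors(uid):
                if skeleton.substituents(nb)["amino"]:
                    return uid, nb
    raise SubstrateError("no alpha-amino acid motif (C2 amino next to C1 "
                         "carboxyl) on this skeleton")


def apply_deamination(skeleton: CarbonSkeleton,
                      variant: str = "oxidative") -> CarbonSkeleton:
    """Convert the C2 amino group to an oxo group (2-keto acid formation).

    ``oxidative`` is the L-amino acid deaminase reaction (NH3 released,
    1/2 O2 consumed in the emitted reaction); ``dehydrating`` is the
    IlvA-type reaction which additionally removes the hydroxyl at C3.
    """
    if variant not in ("oxidative", "dehydrating"):
        raise CascadeError(f"unknown deaminase variant {variant!r}")
    new = skeleton.copy()
    _, alpha = _alpha_carbon(new)
    if variant == "dehydrating":
        c1 = _alpha_carbon(new)[0]
        beta = [nb for nb in new.neighbors(alpha)
                if nb != c1 and new.substituents(nb)["hydroxyl"]]
        if not beta:
            raise SubstrateError(
                "dehydrating deamination requires a hydroxyl at C3")
        new.remove_substituent(beta[0], "hydroxyl")
    new.replace_substituent(alpha, "amino", "oxo")
    return new


def _keto_acid_motif(skeleton: CarbonSkeleton) -> Tuple[int, int]:
    """(carboxyl carbon uid, 2-oxo carbon uid) of a 2-keto acid."""
    for uid in skeleton.carbons():
        if skeleton.substituents(uid)["carboxyl"]:
            for nb in skeleton.neighbors(uid):
                if skeleton.substituents(nb)["oxo"]:
                    return uid, nb
    raise SubstrateError("no 2-oxo-acid motif (oxo adjacent to carboxyl) "
                         "on this skeleton")


def apply_decarboxylation(skeleton: CarbonSkeleton) -> CarbonSkeleton:
    """Remove C1 as CO2; the former C2 oxo becomes an aldehyde carbon."""
    new = skeleton.copy()
    c1, _ = _keto_acid_motif(new)
    new.remove_carbon(c1)
    new.validate()
    return new


def apply_reduction(skeleton: CarbonSkeleton) -> CarbonSkeleton:
    """Reduce the aldehyde carbon (terminal oxo with an H) to CH2-OH."""
    new = skeleton.copy()
    for uid in new.carbons():
        if new.substituents(uid)["oxo"] and new.implicit_h(uid) >= 1:
            new.replace_substituent(uid, "oxo", "hydroxyl")
            return new
    raise SubstrateError("no aldehyde carbon to reduce")


def apply_decarboxylation_reduction(skeleton: CarbonSkeleton
                                    ) -> CarbonSkeleton:
    """The lumped DR step: decarboxylation followed by NADPH reduction."""
    return apply_reduction(apply_decarboxylation(skeleton))


# ---------------------------------------------------------------------------
# reaction emission


def _step_reaction(rxn_id: str, substrate: Compound, product: Compound,
                   step: str, enzyme: Optional[str]) -> Reaction:
    half = Fraction(1, 2)
    if step == "H":
        stoich = {substrate.id: -1, "akg": -1, "o2": -1,
                  product.id: 1, "succ": 1, "co2": 1}
        cls = "hydroxylase"
        display = (f"{substrate.name} + 2-oxoglutarate + O2 -> "
                   f"{product.name} + succinate + CO2")
    elif step == "D":
        stoich = {substrate.id: -1, "o2": -half, product.id: 1, "nh4": 1}
        cls = "deaminase_oxidative"
        display = f"{substrate.name} + 1/2 O2 -> {product.name} + NH3"
    elif step == "Dd":
        stoich = {substrate.id: -1, product.id: 1, "nh4": 1}
        cls = "deaminase_dehydrating"
        display = f"{substrate.name} -> {product.name} + NH3 (+ H2O)"
    elif step == "Dc":
        stoich = {substrate.id: -1, "h": -1, product.id: 1, "co2": 1}
        cls = "decarboxylase"
        display = f"{substrate.name} -> {product.name} + CO2"
    elif step == "R":
        stoich = {substrate.id: -1, "nadph": -1, "h": -1,
                  product.id: 1, "nadp": 1}
        cls = "reductase"
        display = f"{substrate.name} + NADPH + H+ -> {product.name} + NADP+"
    else:
        raise CascadeError(f"unknown step {step!r}")
    name = f"{cls}{' (' + enzyme + ')' if enzyme else ''}"
    return Reaction(id=rxn_id, stoichiometry={k: Fraction(v)
                                              for k, v in stoich.items()},
                    enzyme_class=cls, name=name, display=display)


# ---------------------------------------------------------------------------
# cascade specification and pathway


@dataclass
class CascadeSpec:
    """One substrate x hydroxylation-position cascade configuration."""

    substrate_id: str
    position: str
    deaminase_variant: str = "oxidative"
    hydroxylase: Optional[str] = None
    deaminase: Optional[str] = "AAD"
    decarboxylase: Optional[str] = "KDC"
    reductase: Optional[str] = "YqhD"
    expected_product: str = ""

    def __post_init__(self) -> None:
        self.position = POSITION_ALIASES.get(self.position, self.position)

    def validate(self, registry: CompoundRegistry) -> None:
        if self.substrate_id not in SUBSTRATE_IDS:
            raise CascadeError(f"unknown substrate {self.substrate_id!r}")
        uid = substrate_position_uid(registry, self.substrate_id,
                                     self.position)
        sk = registry[self.substrate_id].skeleton
        assert sk is not None
        subs = sk.substituents(uid)
        if subs["hydroxyl"] or subs["oxo"] or subs["carboxyl"]:
            raise PositionError(
                f"position {self.position} of {self.substrate_id} is "
                "already substituted")
        if self.deaminase_variant == "dehydrating":
            # needs the native beta-OH (threonine-type substrate)
            c3 = [u for u in sk.carbons()
                  if sk.substituents(u)["hydroxyl"]]
            if not c3:
                raise SubstrateError(
                    "dehydrating deaminase requires a substrate with a "
                    "native beta-hydroxyl (threonine)")
        if self.position == "C3" and self.hydroxylase is None:
            warnings.warn(
                "no enzyme configured for beta (C3) hydroxylation in the "
                "shipped table", stacklevel=2)


@dataclass
class Pathway:
    """A fully built four-step cascade with balanced reactions."""

    reactions: List[Reaction]
    intermediates: List[Compound]
    product: Compound
    provenance: CascadeSpec
    substrate: Compound

    def all_compound_ids(self) -> List[str]:
        out = []
        for rx in self.reactions:
            out.extend(rx.stoichiometry)
        return sorted(set(out))

    def overall_reaction(self) -> Reaction:
        """Sum of the step reactions (intermediates cancel)."""
        stoich: Dict[str, Fraction] = {}
        for rx in self.reactions:
            for cid, v in rx.stoichiometry.items():
                stoich[cid] = stoich.get(cid, Fraction(0)) + v
        return Reaction(id=f"{self.provenance.substrate_id}_"
                           f"{self.provenance.position}_overall",
                        stoichiometry=stoich, enzyme_class="other")


def build_cascade(spec: CascadeSpec,
                  registry: Optional[CompoundRegistry] = None) -> Pathway:
    """Build the four-step pathway for a cascade spec.

    Steps are always emitted in the platform order hydroxylation ->
    deamination -> decarboxylation -> reduction (for threonine the
    dehydrating deaminase precedes decarboxylation by construction);
    alternative reaction orders are the business of the route-analysis
    layer, not the builder.
    """
    registry = registry or CompoundRegistry()
    spec.validate(registry)
    substrate = registry[spec.substrate_id]
    uid = substrate_position_uid(registry, spec.substrate_id, spec.position)
    sk = substrate.skeleton
    assert sk is not None

    d_step = "Dd" if spec.deaminase_variant == "dehydrating" else "D"
    plan = [("H", spec.hydroxylase, lambda s: apply_hydroxylation(s, uid)),
            (d_step, spec.deaminase,
             lambda s: apply_deamination(s, spec.deaminase_variant)),
            ("Dc", spec.decarboxylase, apply_decarboxylation),
            ("R", spec.reductase, apply_reduction)]

    reactions: List[Reaction] = []
    intermediates: List[Compound] = []
    current_cpd, current_sk = substrate, sk
    prefix = f"{spec.substrate_id}_{spec.position}"
    for step, enzyme, transform in plan:
        next_sk = transform(current_sk)
        next_cpd = registry.get_or_create(next_sk)
        reactions.append(_step_reaction(f"{prefix}_{step}", current_cpd,
                                        next_cpd, step, enzyme))
        intermediates.append(next_cpd)
        current_cpd, current_sk = next_cpd, next_sk

    product = intermediates.pop()
    psk = product.skeleton
    assert psk is not None
    if (psk.count("hydroxyl") != 2 or psk.count("amino")
            or psk.count("carboxyl") or psk.count("oxo")):
        raise CascadeError(
            f"cascade product {product.id} is not a diol: {psk.formula()}")
    if len(psk.carbons()) != len(sk.carbons()) - 1:
        raise CascadeError("product must have substrate carbons - 1")
    return Pathway(reactions=reactions, intermediates=intermediates,
                   product=product, provenance=spec, substrate=substrate)


# ---------------------------------------------------------------------------
# shipped configuration and product derivation


def load_config(source) -> List[CascadeSpec]:
    """Load cascade specs from a TSV/YAML file path or file-like object."""
    import pathlib
    if hasattr(source, "read"):
        text, suffix = source.read(), ".tsv"
    else:
        p = pathlib.Path(source)
        text, suffix = p.read_text(), p.suffix.lower()
    if suffix in (".yaml", ".yml"):
        import yaml
        rows = yaml.safe_load(text)
    else:
        rows = list(csv.DictReader(io.StringIO(text), delimiter="\t"))
    specs = []
    for r in rows:
        specs.append(CascadeSpec(
            substrate_id=r["substrate"], position=r["position"],
            deaminase_variant=r.get("deaminase_variant", "oxidative"),
            hydroxylase=r.get("hydroxylase") or None,
            deaminase=r.get("deaminase") or None,
            decarboxylase=r.get("decarboxylase") or None,
            reductase=r.get("reductase") or None,
            expected_product=r.get("product", "")))
    return specs


def default_config() -> List[CascadeSpec]:
    """The shipped substrate x position table (ten cascades, ten diols)."""
    text = resources.files("dioldesign.data").joinpath(
        "cascade_config.tsv").read_text()
    return load_config(io.StringIO(text))


def reference_bdo_pathway(registry: Optional[CompoundRegistry] = None
                          ) -> Tuple[List[Reaction],
                                     Dict[str, Compound], Compound]:
    """The reference reductive pathway succinate -> 1,4-butanediol.

    The classic comparison pathway: both hydroxyls are formed reductively
    -- CoA activation of one carboxyl (at ATP expense), CoA transfer for
    the other (from acetyl-CoA), and four sequential NADH reductions
    through the semialdehyde / 4-hydroxybutyrate / aldehyde intermediates.
    Net cost: 1 ATP and 4 NAD(P)H per mole of diol, against which the
    oxidative-hydroxylation platform (1 NADPH, 0 ATP) is benchmarked.

    Returns (reactions, compound lookup, product); the compound lookup
    marks the backbone intermediates as pathway-role species so the
    chained ledger accounting applies.
    """
    registry = registry or CompoundRegistry()
    compounds: Dict[str, Compound] = dict(registry.compounds)
    # CoA thioester of 4-hydroxybutyrate (no skeleton: carries the CoA moiety)
    compounds["4hbcoa"] = Compound(
        id="4hbcoa", name="4-hydroxybutyryl-CoA",
        formula={"C": 25, "H": 38, "N": 7, "O": 18, "P": 3, "S": 1},
        charge=-4, role="pathway")
    from dataclasses import replace as _replace
    for cid in ("succ", "succoa"):
        compounds[cid] = _replace(compounds[cid], role="pathway",
                                  skeleton=None)
    steps = [
        ("BDO1", "succinyl-CoA synthetase (CoA activation, ATP)",
         "1 succ + 1 atp + 1 coa -> 1 succoa + 1 adp + 1 pi"),
        ("BDO2", "succinyl-CoA reductase",
         "1 succoa + 1 nadh + 1 h -> 1 sucsal + 1 coa + 1 nad"),
        ("BDO3", "succinate-semialdehyde reductase",
         "1 sucsal + 1 nadh + 1 h -> 1 4hb + 1 nad"),
        ("BDO4", "4-hydroxybutyryl-CoA transferase (from acetyl-CoA)",
         "1 4hb + 1 accoa -> 1 4hbcoa + 1 ac"),
        ("BDO5", "4-hydroxybutyryl-CoA reductase",
         "1 4hbcoa + 1 nadh + 1 h -> 1 4hba + 1 coa + 1 nad"),
        ("BDO6", "4-hydroxybutyraldehyde reductase",
         "1 4hba + 1 nadh + 1 h -> 1 14bdo + 1 nad"),
    ]
    from .chem import parse_equation
    reactions = []
    for rid, name, eq in steps:
        stoich, _ = parse_equation(eq)
        reactions.append(Reaction(id=rid, stoichiometry=stoich,
                                  enzyme_class="other", name=name))
    return reactions, compounds, compounds["14bdo"]


def enumerate_products(config: Optional[Sequence[CascadeSpec]] = None,
                       registry: Optional[CompoundRegistry] = None
                       ) -> Dict[str, Compound]:
    """Derive the de-duplicated diol product set of a configuration.

    Returns canonical key -> product compound.  Duplicate cascade entries
    (or different cascades converging on the same diol) count once.
    """
    registry = registry or CompoundRegistry()
    products: Dict[str, Compound] = {}
    for spec in (default_config() if config is None else config):
        pw = build_cascade(spec, registry)
        assert pw.product.key is not None
        products[pw.product.key] = pw.product
    return products
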