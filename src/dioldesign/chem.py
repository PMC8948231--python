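"""Compound and reaction primitives for amino-acid-derived diol pathways.

This module provides the small-molecule data model the rest of the package
is built on: an explicit carbon-skeleton representation for the C3-C6
amino-acid / keto-acid / aldehyde / diol chemotypes, compounds with element
formulas and charges, reactions with exact rational stoichiometry, element
and charge balance checking, and net cofactor accounting over multi-step
pathways.

Conventions
-----------
* Carbons are numbered the way amino-acid chemistry numbers them: C1 is the
  carboxyl carbon.  The carboxyl group is modelled as a substituent *on*
  its carbon (C1 *is* the carboxyl carbon).
* All species are written as their pH-7 majority forms: carboxylates are
  deprotonated (charge -1 per carboxyl), amines are protonated ammonium
  groups (+1), free ammonia is carried as NH4+.  With these species the
  cascade reactions balance exactly in every element and in charge, with
  explicit H+ where needed.
* Stoichiometric coefficients are :class:`fractions.Fraction`, so "1/2 O2"
  is represented without floating-point drift.  Negative = consumed.
"""

from __future__ import annotations

import csv
import io
from collections import Counter, deque
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple


class ChemError(Exception):
    """Base class for chemistry-layer errors."""


class SkeletonError(ChemError):
    """Invalid carbon skeleton (valence, substituent rules, connectivity)."""


class UnknownCompoundError(ChemError, LookupError):
    """A reaction references a compound id that is not in the lookup set."""


class PathwayStructureError(ChemError):
    """A reaction list does not chain main-product -> main-substrate."""


# bond orders each substituent occupies on its carbon; the carboxyl group
# (=O plus -O(-)) takes three of the four valences
_BOND_ORDER = {"carboxyl": 3, "amino": 1, "hydroxyl": 1, "oxo": 2}

SUBSTITUENTS = tuple(sorted(_BOND_ORDER))


class CarbonSkeleton:
    """An acyclic carbon backbone with substituents.

    Internally a free tree over carbon atoms with persistent integer uids,
    so a position on a substrate keeps its identity through the cascade
    transforms (hydroxylation, deamination, decarboxylation) even though
    the IUPAC numbering of the molecule changes.  Hydrogens are implicit.
    """

    def __init__(self) -> None:
        self._subs: Dict[int, Counter] = {}
        self._adj: Dict[int, set] = {}
        self._next_uid = 1

    # -- construction -------------------------------------------------

    def add_carbon(self, attach_to: Optional[int] = None,
                   substituents: Iterable[str] = ()) -> int:
        uid = self._next_uid
        self._next_uid += 1
        self._subs[uid] = Counter(substituents)
        self._adj[uid] = set()
        if attach_to is not None:
            if attach_to not in self._subs:
                raise SkeletonError(f"no carbon with uid {attach_to}")
            self._adj[uid].add(attach_to)
            self._adj[attach_to].add(uid)
        elif len(self._subs) > 1:
            raise SkeletonError("non-first carbon must attach to the tree")
        for s in self._subs[uid]:
            if s not in _BOND_ORDER:
                raise SkeletonError(f"unknown substituent {s!r}")
        return uid

    @classmethod
    def chain(cls, n: int, substituents: Mapping[int, Iterable[str]] = {},
              ) -> Tuple["CarbonSkeleton", List[int]]:
        """Build a linear chain of ``n`` carbons; returns (skeleton, uids).

        ``substituents`` maps 1-based chain position -> substituent names.
        """
        sk = cls()
        uids: List[int] = []
        for i in range(1, n + 1):
            uid = sk.add_carbon(attach_to=uids[-1] if uids else None,
                                substituents=substituents.get(i, ()))
            uids.append(uid)
        sk.validate()
        return sk, uids

    def add_branch(self, at: int, n: int = 1) -> List[int]:
        """Attach a linear branch of ``n`` carbons at carbon ``at``."""
        uids: List[int] = []
        anchor = at
        for _ in range(n):
            anchor = self.add_carbon(attach_to=anchor)
            uids.append(anchor)
        return uids

    def copy(self) -> "CarbonSkeleton":
        new = CarbonSkeleton()
        new._subs = {u: Counter(c) for u, c in self._subs.items()}
        new._adj = {u: set(v) for u, v in self._adj.items()}
        new._next_uid = self._next_uid
        return new

    # -- editing (used by the cascade transforms) ----------------------

    def add_substituent(self, uid: int, sub: str) -> None:
        self._check_uid(uid)
        if sub not in _BOND_ORDER:
            raise SkeletonError(f"unknown substituent {sub!r}")
        self._subs[uid][sub] += 1
        self.validate()

    def remove_substituent(self, uid: int, sub: str) -> None:
        self._check_uid(uid)
        if self._subs[uid][sub] < 1:
            raise SkeletonError(f"carbon {uid} has no {sub} to remove")
        self._subs[uid][sub] -= 1
        if self._subs[uid][sub] == 0:
            del self._subs[uid][sub]

    def replace_substituent(self, uid: int, old: str, new: str) -> None:
        self.remove_substituent(uid, old)
        self._subs[uid][new] += 1
        self.validate()

    def remove_carbon(self, uid: int) -> None:
        """Remove a terminal (leaf) carbon, e.g. the carboxyl carbon lost
        as CO2 in a decarboxylation."""
        self._check_uid(uid)
        if len(self._adj[uid]) > 1:
            raise SkeletonError("only terminal carbons can be removed")
        for nb in self._adj[uid]:
            self._adj[nb].discard(uid)
        del self._adj[uid]
        del self._subs[uid]

    # -- queries -------------------------------------------------------

    def carbons(self) -> List[int]:
        return sorted(self._subs)

    def neighbors(self, uid: int) -> List[int]:
        self._check_uid(uid)
        return sorted(self._adj[uid])

    def substituents(self, uid: int) -> Counter:
        self._check_uid(uid)
        return Counter(self._subs[uid])

    def implicit_h(self, uid: int) -> int:
        self._check_uid(uid)
        used = len(self._adj[uid]) + sum(
            _BOND_ORDER[s] * n for s, n in self._subs[uid].items())
        return 4 - used

    def count(self, sub: str) -> int:
        return sum(c[sub] for c in self._subs.values())

    def distance(self, a: int, b: int) -> int:
        """Topological distance (number of C-C bonds) between two carbons."""
        self._check_uid(a), self._check_uid(b)
        seen = {a}
        frontier = deque([(a, 0)])
        while frontier:
            u, d = frontier.popleft()
            if u == b:
                return d
            for nb in self._adj[u]:
                if nb not in seen:
                    seen.add(nb)
                    frontier.append((nb, d + 1))
        raise SkeletonError("disconnected skeleton")

    def _check_uid(self, uid: int) -> None:
        if uid not in self._subs:
            raise SkeletonError(f"no carbon with uid {uid}")

    def validate(self) -> None:
        """Check the skeleton invariants; raise :class:`SkeletonError`.

        Every carbon's valence accounting (backbone bonds + substituent
        bond orders + implicit H) must equal four, and a carbon carries at
        most one of {carboxyl, oxo}.
        """
        if not self._subs:
            raise SkeletonError("empty skeleton")
        # connectivity + acyclicity
        seen = {next(iter(self._subs))}
        frontier = deque(seen)
        nedges = sum(len(v) for v in self._adj.values()) // 2
        while frontier:
            u = frontier.popleft()
            for nb in self._adj[u]:
                if nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        if len(seen) != len(self._subs) or nedges != len(self._subs) - 1:
            raise SkeletonError("skeleton must be a connected acyclic tree")
        for uid, subs in self._subs.items():
            if self.implicit_h(uid) < 0:
                raise SkeletonError(f"carbon {uid} exceeds valence 4")
            if subs["carboxyl"] + subs["oxo"] > 1:
                raise SkeletonError(
                    f"carbon {uid}: at most one of carboxyl/oxo per carbon")
            if subs["carboxyl"] and (subs["hydroxyl"] or subs["amino"]):
                raise SkeletonError(
                    f"carbon {uid}: carboxyl carbon carries no other group")

    # -- derived chemistry --------------------------------------------

    def formula(self) -> Dict[str, int]:
        """Element counts of the pH-7 majority species."""
        c = len(self._subs)
        h = sum(self.implicit_h(u) for u in self._subs)
        o = n = 0
        for subs in self._subs.values():
            h += 3 * subs["amino"] + subs["hydroxyl"]
            o += 2 * subs["carboxyl"] + subs["hydroxyl"] + subs["oxo"]
            n += subs["amino"]
        out = {"C": c, "H": h}
        if n:
            out["N"] = n
        if o:
            out["O"] = o
        return out

    def charge(self) -> int:
        """Net charge of the majority species: -1 per carboxylate, +1 per
        ammonium group."""
        return self.count("amino") - self.count("carboxyl")

    # -- canonical identity -------------------------------------------

    def canonical_key(self) -> str:
        """Canonical text token for the molecule this skeleton represents.

        Uses AHU canonical encoding of the free tree rooted at its
        center(s), with each carbon labelled by its sorted substituent
        multiset.  The token is therefore invariant under renumbering,
        branch-enumeration order and mirror-equivalent numbering, and
        distinct trees give distinct tokens.
        """
        def label(uid: int) -> str:
            subs = self._subs[uid]
            return "".join(f"{s[0]}{subs[s]}" for s in sorted(subs) if subs[s])

        def encode(uid: int, parent: Optional[int]) -> str:
            kids = sorted(encode(nb, uid) for nb in self._adj[uid]
                          if nb != parent)
            return "(" + label(uid) + "".join(kids) + ")"

        centers = self._centers()
        if len(centers) == 2:
            body = "=".join(sorted((encode(centers[0], centers[1]),
                                    encode(centers[1], centers[0]))))
        else:
            body = encode(centers[0], None)
        f = self.formula()
        head = "".join(f"{el}{f[el]}" for el in ("C", "H", "N", "O") if el in f)
        return f"{head}:{body}"

    def _centers(self) -> List[int]:
        """Center(s) of the free tree (1 or 2 vertices)."""
        degree = {u: len(self._adj[u]) for u in self._subs}
        leaves = deque(u for u, d in degree.items() if d <= 1)
        remaining = len(self._subs)
        while remaining > 2:
            for _ in range(len(leaves)):
                u = leaves.popleft()
                remaining -= 1
                for nb in self._adj[u]:
                    degree[nb] -= 1
                    if degree[nb] == 1:
                        leaves.append(nb)
        return sorted(leaves)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<CarbonSkeleton {self.canonical_key()}>"


# ---------------------------------------------------------------------------
# compounds


@dataclass
class Compound:
    """A chemical species: pathway intermediate, cofactor or exchangeable.

    ``formula`` maps element symbol -> count for the pH-7 majority species;
    ``charge`` is its net charge.  Pathway compounds carry a
    :class:`CarbonSkeleton` from which formula and charge are derived (and
    validated against); cofactors carry none.
    """

    id: str
    name: str
    formula: Dict[str, int]
    charge: int = 0
    role: str = "pathway"          # pathway | cofactor | exchangeable
    skeleton: Optional[CarbonSkeleton] = None

    def __post_init__(self) -> None:
        if self.role not in ("pathway", "cofactor", "exchangeable"):
            raise ChemError(f"bad role {self.role!r} for compound {self.id}")
        if self.skeleton is not None:
            derived = self.skeleton.formula()
            if derived != self.formula:
                raise ChemError(
                    f"{self.id}: declared formula {self.formula} does not "
                    f"match skeleton-derived {derived}")
            if self.skeleton.charge() != self.charge:
                raise ChemError(
                    f"{self.id}: declared charge {self.charge} does not "
                    f"match skeleton-derived {self.skeleton.charge()}")

    @classmethod
    def from_skeleton(cls, id: str, name: str, skeleton: CarbonSkeleton,
                      role: str = "pathway") -> "Compound":
        return cls(id=id, name=name, formula=skeleton.formula(),
                   charge=skeleton.charge(), role=role, skeleton=skeleton)

    @property
    def key(self) -> Optional[str]:
        return self.skeleton.canonical_key() if self.skeleton else None


def cofactor_compounds() -> Dict[str, Compound]:
    """The standard cofactor / inorganic species set (BiGG-style formulas,
    pH-7 majority charges)."""
    spec = [
        # id, name, formula, charge
        ("h2o", "H2O", {"H": 2, "O": 1}, 0),
        ("h", "H+", {"H": 1}, 1),
        ("o2", "O2", {"O": 2}, 0),
        ("co2", "CO2", {"C": 1, "O": 2}, 0),
        ("nh4", "NH4+ (ammonia pool)", {"H": 4, "N": 1}, 1),
        ("pi", "phosphate", {"H": 1, "O": 4, "P": 1}, -2),
        ("akg", "2-oxoglutarate", {"C": 5, "H": 4, "O": 5}, -2),
        ("succ", "succinate", {"C": 4, "H": 4, "O": 4}, -2),
        ("nad", "NAD+", {"C": 21, "H": 26, "N": 7, "O": 14, "P": 2}, -1),
        ("nadh", "NADH", {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2}, -2),
        ("nadp", "NADP+", {"C": 21, "H": 25, "N": 7, "O": 17, "P": 3}, -3),
        ("nadph", "NADPH", {"C": 21, "H": 26, "N": 7, "O": 17, "P": 3}, -4),
        ("atp", "ATP", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}, -4),
        ("adp", "ADP", {"C": 10, "H": 12, "N": 5, "O": 10, "P": 2}, -3),
        ("coa", "coenzyme A",
         {"C": 21, "H": 32, "N": 7, "O": 16, "P": 3, "S": 1}, -4),
        ("accoa", "acetyl-CoA",
         {"C": 23, "H": 34, "N": 7, "O": 17, "P": 3, "S": 1}, -4),
        ("ac", "acetate", {"C": 2, "H": 3, "O": 2}, -1),
        ("succoa", "succinyl-CoA",
         {"C": 25, "H": 35, "N": 7, "O": 19, "P": 3, "S": 1}, -5),
        ("glc", "D-glucose", {"C": 6, "H": 12, "O": 6}, 0),
        ("glu", "L-glutamate", {"C": 5, "H": 8, "N": 1, "O": 4}, -1),
        ("pyr", "pyruvate", {"C": 3, "H": 3, "O": 3}, -1),
    ]
    return {i: Compound(id=i, name=n, formula=f, charge=c, role="cofactor")
            for i, n, f, c in spec}


# ---------------------------------------------------------------------------
# reactions


ENZYME_CLASSES = ("hydroxylase", "deaminase_oxidative", "deaminase_dehydrating",
                  "decarboxylase", "reductase", "other")


@dataclass
class Reaction:
    """A stoichiometric reaction over compound ids.

    Coefficients are exact :class:`fractions.Fraction`; negative means
    consumed.  ``display`` optionally preserves the form a reaction is
    printed in elsewhere (e.g. with NH3 instead of NH4+); the stored
    stoichiometry is always the fully balanced pH-7 form.
    """

    id: str
    stoichiometry: Dict[str, Fraction]
    enzyme_class: str = "other"
    reversible: bool = False
    name: str = ""
    display: str = ""

    def __post_init__(self) -> None:
        if self.enzyme_class not in ENZYME_CLASSES:
            raise ChemError(f"unknown enzyme class {self.enzyme_class!r}")
        self.stoichiometry = {c: Fraction(v)
                              for c, v in self.stoichiometry.items()
                              if Fraction(v) != 0}

    def substrates(self) -> List[str]:
        return sorted(c for c, v in self.stoichiometry.items() if v < 0)

    def products(self) -> List[str]:
        return sorted(c for c, v in self.stoichiometry.items() if v > 0)

    def reverse(self) -> "Reaction":
        return replace(self, id=self.id + "_rev",
                       stoichiometry={c: -v
                                      for c, v in self.stoichiometry.items()})

    def equation(self) -> str:
        def side(items: Iterable[Tuple[str, Fraction]]) -> str:
            parts = [f"{abs(v)} {c}" for c, v in items]
            return " + ".join(parts) if parts else "0"
        lhs = [(c, v) for c, v in sorted(self.stoichiometry.items()) if v < 0]
        rhs = [(c, v) for c, v in sorted(self.stoichiometry.items()) if v > 0]
        arrow = "<->" if self.reversible else "->"
        return f"{side(lhs)} {arrow} {side(rhs)}"


@dataclass
class BalanceReport:
    """Per-element residuals (sum of coeff * element count) and net charge
    of a reaction; all-zero residuals means the reaction is balanced."""

    reaction_id: str
    residuals: Dict[str, Fraction]
    charge_residual: Fraction

    @property
    def balanced(self) -> bool:
        return (all(v == 0 for v in self.residuals.values())
                and self.charge_residual == 0)

    def __str__(self) -> str:
        if self.balanced:
            return f"{self.reaction_id}: balanced"
        bad = {e: str(v) for e, v in self.residuals.items() if v != 0}
        return (f"{self.reaction_id}: residuals {bad}, "
                f"charge {self.charge_residual}")


def element_balance(reaction: Reaction,
                    compounds: Mapping[str, Compound]) -> BalanceReport:
    """Check element and charge conservation of a reaction.

    Returns a :class:`BalanceReport`; raises :class:`UnknownCompoundError`
    if the reaction references a compound id missing from ``compounds``.
    """
    residuals: Dict[str, Fraction] = {}
    charge = Fraction(0)
    for cid, coeff in reaction.stoichiometry.items():
        if cid not in compounds:
            raise UnknownCompoundError(
                f"reaction {reaction.id}: unknown compound {cid!r}")
        cpd = compounds[cid]
        for el, n in cpd.formula.items():
            residuals[el] = residuals.get(el, Fraction(0)) + coeff * n
        charge += coeff * cpd.charge
    return BalanceReport(reaction.id, residuals, charge)


def assert_balanced(reactions: Iterable[Reaction],
                    compounds: Mapping[str, Compound]) -> None:
    bad = [str(r) for rx in reactions
           if not (r := element_balance(rx, compounds)).balanced]
    if bad:
        raise ChemError("unbalanced reactions: " + "; ".join(bad))


# ---------------------------------------------------------------------------
# cofactor ledger


#: ledger species and the labels they are reported under; positive values
#: mean net consumption per mole of product
LEDGER_SPECIES = {
    "atp": "ATP", "nadh": "NADH", "nadph": "NADPH", "o2": "O2",
    "co2": "CO2", "nh4": "NH3", "akg": "alpha-ketoglutarate",
    "succ": "succinate",
}


@dataclass
class CofactorLedger:
    """Net moles of energy/redox/byproduct species per mole of product.

    Positive = consumed, negative = produced.  The paper's "NH3" pool is
    carried as NH4+ internally and reported under the NH3 label.
    """

    atp: Fraction = Fraction(0)
    nadh: Fraction = Fraction(0)
    nadph: Fraction = Fraction(0)
    o2: Fraction = Fraction(0)
    co2: Fraction = Fraction(0)
    nh3: Fraction = Fraction(0)
    akg: Fraction = Fraction(0)
    succinate: Fraction = Fraction(0)

    _FIELD_FOR = {"atp": "atp", "nadh": "nadh", "nadph": "nadph",
                  "o2": "o2", "co2": "co2", "nh4": "nh3", "akg": "akg",
                  "succ": "succinate"}

    def __add__(self, other: "CofactorLedger") -> "CofactorLedger":
        return CofactorLedger(**{f: getattr(self, f) + getattr(other, f)
                                 for f in self._FIELD_FOR.values()})

    @property
    def nad_p_h(self) -> Fraction:
        """Total NAD(P)H consumption, the quantity the reductive-pathway
        comparison is stated in."""
        return self.nadh + self.nadph

    def as_dict(self) -> Dict[str, float]:
        return {LEDGER_SPECIES[k]: float(getattr(self, f))
                for k, f in self._FIELD_FOR.items()}


def _main_pathway_species(reaction: Reaction,
                          compounds: Mapping[str, Compound],
                          consumed: bool) -> List[str]:
    sign = -1 if consumed else 1
    return [c for c, v in reaction.stoichiometry.items()
            if sign * v > 0 and c in compounds
            and compounds[c].role == "pathway"]


def net_cofactor_ledger(pathway: Sequence[Reaction], product: Compound,
                        compounds: Mapping[str, Compound]) -> CofactorLedger:
    """Net cofactor consumption of a chained pathway per mole of product.

    The pathway must chain: each step's main (pathway-role) product is the
    next step's main substrate, and the last step must produce ``product``.
    An empty pathway (product identical to substrate) yields the zero
    ledger.
    """
    for rx in pathway:
        if not element_balance(rx, compounds).balanced:
            raise ChemError(f"reaction {rx.id} is not balanced")
    for prev, nxt in zip(pathway, pathway[1:]):
        made = set(_main_pathway_species(prev, compounds, consumed=False))
        used = set(_main_pathway_species(nxt, compounds, consumed=True))
        if not made & used:
            raise PathwayStructureError(
                f"steps {prev.id} -> {nxt.id} do not chain: {sorted(made)} "
                f"vs {sorted(used)}")
    if pathway:
        produced = sum(rx.stoichiometry.get(product.id, Fraction(0))
                       for rx in pathway)
        if produced != 1:
            raise PathwayStructureError(
                f"pathway produces {produced} mol of {product.id}, "
                "expected exactly 1")
    ledger = CofactorLedger()
    for rx in pathway:
        for species, fieldname in CofactorLedger._FIELD_FOR.items():
            coeff = rx.stoichiometry.get(species, Fraction(0))
            # positive ledger entry = consumed
            setattr(ledger, fieldname, getattr(ledger, fieldname) - coeff)
    return ledger


def canonical_key(skeleton: CarbonSkeleton) -> str:
    """Canonical token of a skeleton (see
    :meth:`CarbonSkeleton.canonical_key`)."""
    return skeleton.canonical_key()


# ---------------------------------------------------------------------------
# flat-table serialization


def _format_formula(formula: Mapping[str, int]) -> str:
    return "".join(f"{el}{n}" for el, n in sorted(formula.items()))


def _parse_formula(text: str) -> Dict[str, int]:
    import re
    out: Dict[str, int] = {}
    for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        if el:
            out[el] = out.get(el, 0) + (int(n) if n else 1)
    return out


def compounds_to_tsv(compounds: Iterable[Compound]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["id", "name", "formula", "charge", "role"])
    for c in sorted(compounds, key=lambda c: c.id):
        w.writerow([c.id, c.name, _format_formula(c.formula), c.charge,
                    c.role])
    return buf.getvalue()


def compounds_from_tsv(text: str) -> Dict[str, Compound]:
    out: Dict[str, Compound] = {}
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        out[row["id"]] = Compound(
            id=row["id"], name=row["name"],
            formula=_parse_formula(row["formula"]),
            charge=int(row["charge"]), role=row["role"])
    return out


def parse_equation(text: str) -> Tuple[Dict[str, Fraction], bool]:
    """Parse ``"1 leu + 1 akg + 1 o2 -> 1 4ohleu + ..."`` equations.

    Coefficients may be integers or fractions like ``1/2``; a bare
    compound id counts as coefficient 1.  Returns (stoichiometry,
    reversible).
    """
    reversible = "<->" in text
    lhs, _, rhs = text.partition("<->" if reversible else "->")
    if not rhs.strip() and not reversible:
        raise ChemError(f"equation has no arrow: {text!r}")
    stoich: Dict[str, Fraction] = {}

    def add(side: str, sign: int) -> None:
        side = side.strip()
        if side in ("", "0"):
            return
        for term in side.split("+"):
            parts = term.split()
            if not parts:
                raise ChemError(f"empty term in equation {text!r}")
            if len(parts) == 1:
                coeff, cid = Fraction(1), parts[0]
            else:
                coeff, cid = Fraction(parts[0]), parts[1]
            stoich[cid] = stoich.get(cid, Fraction(0)) + sign * coeff

    add(lhs, -1)
    add(rhs, +1)
    return stoich, reversible


def reactions_to_tsv(reactions: Iterable[Reaction]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["id", "equation", "enzyme_class", "reversible"])
    for r in reactions:
        w.writerow([r.id, r.equation(), r.enzyme_class, int(r.reversible)])
    return buf.getvalue()


def reactions_from_tsv(text: str) -> List[Reaction]:
    out = []
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        stoich, rev = parse_equation(row["equation"])
        out.append(Reaction(id=row["id"], stoichiometry=stoich,
                            enzyme_class=row.get("enzyme_class", "other"),
                            reversible=bool(int(row.get("reversible", 0)))))
    return out
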