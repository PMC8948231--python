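"""Group-contribution thermodynamics for cascade routes.

Transformed standard formation energies (dGf', kJ/mol) of the
skeleton-bearing pathway compounds are estimated additively from a frozen,
versioned group-contribution table; cofactors and anchored metabolites
carry direct per-compound overrides.  Reaction energies are

    drG' = sum_i nu_i dGf'(i) + RT sum_i nu_i ln(c_i)

with concentrations from the declared conditions (default: every
metabolite, including dissolved O2 and CO2, at 1 mM -- the dG'm
convention; H+ and H2O are omitted from the concentration term as their
activities are fixed by pH and the solvent).

A route's thermodynamic profile is the sequence of per-step drG' values
plus two scalar summaries:

* bottleneck -- the maximum (least negative) step drG', the step with the
  smallest driving force;
* harmony -- the population standard deviation of the step drG' values, a
  dispersion measure formalising the notion of an ideal profile in which
  every step contributes the same driving force (harmony = 0).
"""

from __future__ import annotations

import csv
import io
import json
import math
import statistics
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .cascade import CompoundRegistry
from .chem import ChemError, Compound, Reaction
from .routes import RouteOrdering

R_GAS = 8.314462618e-3      # kJ mol-1 K-1
KJ_PER_KCAL = 4.184


class CoverageError(ChemError):
    """A compound cannot be decomposed into the table's groups and has no
    override entry."""


@dataclass
class GroupTable:
    """Frozen group-contribution parameter set (kJ/mol)."""

    version: str
    origin: float
    groups: Dict[str, float]
    corrections: Dict[str, float]
    overrides: Dict[str, float]

    @classmethod
    def load(cls, source=None) -> "GroupTable":
        """Load the bundled table, or a table from a path/file object."""
        if source is None:
            text = resources.files("dioldesign.data").joinpath(
                "group_contributions.tsv").read_text()
        elif hasattr(source, "read"):
            text = source.read()
        else:
            text = open(source).read()
        version, origin = "unversioned", 0.0
        groups: Dict[str, float] = {}
        corrections: Dict[str, float] = {}
        overrides: Dict[str, float] = {}
        lines = [ln for ln in text.splitlines()
                 if ln.strip() and not ln.startswith("#")]
        for row in csv.DictReader(io.StringIO("\n".join(lines)),
                                  delimiter="\t"):
            kind, ident = row["kind"], row["id"]
            if kind == "meta" and ident == "version":
                version = row["value_kj_mol"]
                continue
            value = float(row["value_kj_mol"])
            if kind == "origin":
                origin = value
            elif kind == "group":
                groups[ident] = value
            elif kind == "correction":
                corrections[ident] = value
            elif kind == "override":
                overrides[ident] = value
            else:
                raise ChemError(f"unknown table row kind {kind!r}")
        return cls(version, origin, groups, corrections, overrides)

    def dump(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
        w.writerow(["kind", "id", "value_kj_mol"])
        w.writerow(["meta", "version", self.version])
        w.writerow(["origin", "origin", f"{self.origin:.2f}"])
        for section, entries in (("group", self.groups),
                                 ("correction", self.corrections),
                                 ("override", self.overrides)):
            for ident, v in entries.items():
                w.writerow([section, ident, f"{v:.6f}"])
        return buf.getvalue()


def decompose(compound: Compound) -> Dict[str, int]:
    """Group multiset of a skeleton-bearing compound.

    A carboxylate carbon contributes the ``carboxylate`` group (which
    absorbs its carbon unit); every other carbon contributes a backbone
    unit ``C_Hn`` by implicit hydrogen count plus one group per
    substituent.  Nonadditive corrections: one ``hydroxy_carbonyl_1_3``
    per hydroxyl/oxo pair at carbon-carbon distance 2 (the beta-hydroxy
    ketone/aldehyde intramolecular hydrogen bond).
    """
    sk = compound.skeleton
    if sk is None:
        raise CoverageError(
            f"{compound.id} has no skeleton and no override entry")
    counts: Dict[str, int] = {}

    def bump(g: str, n: int = 1) -> None:
        counts[g] = counts.get(g, 0) + n

    for uid in sk.carbons():
        subs = sk.substituents(uid)
        if subs["carboxyl"]:
            bump("carboxylate")
        else:
            bump(f"C_H{sk.implicit_h(uid)}")
        for name, group in (("amino", "amino"), ("hydroxyl", "hydroxyl"),
                            ("oxo", "oxo")):
            if subs[name]:
                bump(group, subs[name])
    carbons = sk.carbons()
    for i, a in enumerate(carbons):
        for b in carbons[i + 1:]:
            pairs = (sk.substituents(a)["hydroxyl"] * sk.substituents(b)["oxo"]
                     + sk.substituents(b)["hydroxyl"]
                     * sk.substituents(a)["oxo"])
            if pairs and sk.distance(a, b) == 2:
                bump("hydroxy_carbonyl_1_3", pairs)
    return counts


def estimate_dfg(compound: Compound, table: GroupTable) -> float:
    """Transformed standard formation energy dGf' (kJ/mol).

    Override entries take precedence; otherwise the skeleton is decomposed
    into groups.  Raises :class:`CoverageError` naming the missing groups
    if the compound is not coverable.
    """
    if compound.id in table.overrides:
        return table.overrides[compound.id]
    counts = decompose(compound)
    known = {**table.groups, **table.corrections}
    missing = sorted(g for g in counts if g not in known)
    if missing:
        raise CoverageError(
            f"{compound.id}: groups not in table v{table.version}: {missing}")
    return table.origin + sum(n * known[g] for g, n in counts.items())


@dataclass
class ThermoConditions:
    """Conditions drG' is evaluated at.

    The bundled table is parameterised at 298.15 K, pH 7.0 and ionic
    strength 0.25 M; pH and ionic strength are declared here for
    traceability and must match the table's parameterisation.  The
    concentration term uses ``default_concentration`` (1 mM, the dG'm
    convention) for every species without an entry in ``concentrations``;
    dissolved O2 and CO2 follow the same aqueous-mM convention by default
    (set explicit entries to use a different gas convention).  H+ and H2O
    never enter the concentration term.
    """

    temperature: float = 298.15
    pH: float = 7.0
    ionic_strength: float = 0.25
    default_concentration: float = 1e-3
    concentrations: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.default_concentration <= 0:
            raise ValueError("default concentration must be positive")

    def concentration(self, compound_id: str) -> float:
        return self.concentrations.get(compound_id,
                                       self.default_concentration)

    @property
    def rt(self) -> float:
        return R_GAS * self.temperature


_FIXED_ACTIVITY = ("h", "h2o")


def reaction_drg(reaction: Reaction, compounds: Mapping[str, Compound],
                 table: GroupTable,
                 conditions: Optional[ThermoConditions] = None) -> float:
    """Transformed reaction energy drG' (kJ/mol) at the given conditions."""
    conditions = conditions or ThermoConditions()
    total = 0.0
    for cid, coeff in reaction.stoichiometry.items():
        if cid not in compounds:
            raise ChemError(f"reaction {reaction.id}: unknown compound {cid}")
        total += float(coeff) * estimate_dfg(compounds[cid], table)
        if cid not in _FIXED_ACTIVITY:
            total += (float(coeff) * conditions.rt
                      * math.log(conditions.concentration(cid)))
    return total


@dataclass
class ProfileStep:
    label: str
    reaction_ids: List[str]
    drg_kj: float

    @property
    def drg_kcal(self) -> float:
        return self.drg_kj / KJ_PER_KCAL


@dataclass
class ThermoProfile:
    """Per-step and cumulative drG' along a route."""

    route_label: str
    steps: List[ProfileStep]
    table_version: str

    @property
    def step_values_kj(self) -> List[float]:
        return [s.drg_kj for s in self.steps]

    @property
    def cumulative_kj(self) -> List[float]:
        out, run = [], 0.0
        for s in self.steps:
            run += s.drg_kj
            out.append(run)
        return out

    @property
    def endpoint_kj(self) -> float:
        return self.cumulative_kj[-1] if self.steps else 0.0

    @property
    def bottleneck_kj(self) -> float:
        """The least negative (smallest driving force) step drG'."""
        return max(self.step_values_kj)

    @property
    def harmony_kj(self) -> float:
        """Population standard deviation of step drG'; 0 iff all steps
        carry the same driving force (the ideal profile)."""
        return statistics.pstdev(self.step_values_kj)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
        w.writerow(["step", "reaction_ids", "drG_kJ", "drG_kcal",
                    "cumulative_kJ"])
        for s, cum in zip(self.steps, self.cumulative_kj):
            w.writerow([s.label, "+".join(s.reaction_ids),
                        f"{s.drg_kj:.3f}", f"{s.drg_kcal:.3f}",
                        f"{cum:.3f}"])
        return buf.getvalue()

    def to_dict(self) -> Dict:
        return {
            "route": self.route_label,
            "table_version": self.table_version,
            "steps": [{"step": s.label, "drG_kJ": s.drg_kj,
                       "drG_kcal": s.drg_kcal} for s in self.steps],
            "cumulative_kJ": self.cumulative_kj,
            "endpoint_kJ": self.endpoint_kj,
            "bottleneck_kJ": self.bottleneck_kj,
            "harmony_kJ": self.harmony_kj,
        }


def cascade_profile(route: RouteOrdering,
                    compounds: Mapping[str, Compound],
                    table: Optional[GroupTable] = None,
                    conditions: Optional[ThermoConditions] = None,
                    split_dr: bool = False) -> ThermoProfile:
    """Thermodynamic profile of a replayed route ordering.

    With ``split_dr`` the lumped DR step is reported as its
    decarboxylation and reduction sub-steps (a four-step profile).
    Raises if the route contains a chemically impossible step (no
    balanced reaction exists for it).
    """
    table = table or GroupTable.load()
    conditions = conditions or ThermoConditions()
    if not route.chemically_possible:
        bad = [r for r in route.resolutions if not r.possible][0]
        raise ChemError(
            f"route {route.label} has no thermodynamic profile: step "
            f"{bad.step} is chemically impossible ({bad.reason})")
    steps: List[ProfileStep] = []
    for res in route.resolutions:
        if split_dr and len(res.reactions) > 1:
            for rx in res.reactions:
                drg = reaction_drg(rx, compounds, table, conditions)
                steps.append(ProfileStep(rx.enzyme_class, [rx.id], drg))
        else:
            drg = sum(reaction_drg(rx, compounds, table, conditions)
                      for rx in res.reactions)
            steps.append(ProfileStep(res.step,
                                     [rx.id for rx in res.reactions], drg))
    return ThermoProfile(route.label, steps, table.version)


class ConsistencyError(ChemError):
    """Profiles claimed to share substrate and product disagree on the
    overall reaction energy (a Hess-additivity violation)."""


@dataclass
class RouteRanking:
    profiles: List[ThermoProfile]
    order: List[str]                 # route labels, best first
    endpoint_kj: float

    def to_dict(self) -> Dict:
        return {"ranking": self.order, "endpoint_kJ": self.endpoint_kj,
                "profiles": [p.to_dict() for p in self.profiles]}


def compare_routes(profiles: Sequence[ThermoProfile],
                   tolerance: float = 1e-6) -> RouteRanking:
    """Rank route profiles over the same overall reaction.

    All cumulative endpoints must agree within ``tolerance`` (same
    substrate and product imply the same overall drG' by Hess's law; a
    mismatch signals an unbalanced route construction).  Ranking is by
    (bottleneck ascending, harmony ascending): the best route has the most
    negative worst step, ties broken by the most even profile.
    """
    if not profiles:
        raise ValueError("no profiles to compare")
    endpoints = [p.endpoint_kj for p in profiles]
    if max(endpoints) - min(endpoints) > tolerance:
        raise ConsistencyError(
            f"route endpoints differ beyond {tolerance} kJ/mol: "
            f"{dict((p.route_label, round(p.endpoint_kj, 6)) for p in profiles)}")
    ranked = sorted(profiles,
                    key=lambda p: (p.bottleneck_kj, p.harmony_kj))
    return RouteRanking(list(profiles), [p.route_label for p in ranked],
                        endpoints[0])
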