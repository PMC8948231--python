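"""Reaction-order enumeration and activity-based feasibility filtering.

With decarboxylation and reduction lumped into a single DR step (the
reduction of the aldehyde always follows the decarboxylation), the
three-step cascade {H = hydroxylation, D = deamination, DR} admits six
reaction orders, labelled R1..R6.  Each ordering is replayed through the
cascade skeleton transforms to resolve the per-step (enzyme, substrate)
pairs; a step whose chemical motif is absent (e.g. DR on a substrate
without the 2-oxo-acid motif) is recorded as chemically impossible.
Orderings are then filtered against an enzyme-substrate activity matrix:
a route survives only if every step's enzyme is active on its actual
substrate.  Activity facts are three-valued (active / inactive / unknown)
because only some pairs were ever assayed; the strict policy treats
unknown as infeasible, the permissive policy as feasible.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field
from importlib import resources
from itertools import permutations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .cascade import (CascadeError, CascadeSpec, CompoundRegistry, Pathway,
                      SubstrateError, apply_deamination,
                      apply_decarboxylation, apply_hydroxylation,
                      apply_reduction, build_cascade, substrate_position_uid,
                      _step_reaction)
from .chem import Compound, Reaction

#: lumped-step labels in the Fig-1b platform order
LUMPED_STEPS = ("H", "D", "DR")

#: the fixed route labelling: R1..R6 in the order the six permutations are
#: conventionally listed (both H-first, then both D-first, then both
#: DR-first)
ROUTE_ORDERINGS: Dict[str, Tuple[str, str, str]] = {
    "R1": ("H", "D", "DR"),
    "R2": ("H", "DR", "D"),
    "R3": ("D", "H", "DR"),
    "R4": ("D", "DR", "H"),
    "R5": ("DR", "H", "D"),
    "R6": ("DR", "D", "H"),
}

ACTIVITY_STATES = ("active", "inactive", "unknown")


class ActivityMatrix:
    """Three-valued (enzyme, substrate) activity lookup.

    Keys are (enzyme id, substrate canonical key); lookups of unrecorded
    pairs return ``"unknown"``, never a default boolean.
    """

    def __init__(self) -> None:
        self._facts: Dict[Tuple[str, str], str] = {}

    def set(self, enzyme_id: str, substrate_key: str, status: str) -> None:
        if status not in ("active", "inactive"):
            raise ValueError(f"status must be active/inactive, got {status!r}")
        self._facts[(enzyme_id, substrate_key)] = status

    def lookup(self, enzyme_id: str, substrate_key: str) -> str:
        return self._facts.get((enzyme_id, substrate_key), "unknown")

    def facts(self) -> Dict[Tuple[str, str], str]:
        return dict(self._facts)

    def copy(self) -> "ActivityMatrix":
        new = ActivityMatrix()
        new._facts = dict(self._facts)
        return new

    @classmethod
    def from_tsv(cls, text: str,
                 registry: CompoundRegistry) -> "ActivityMatrix":
        """Load facts from the shipped TSV format (enzyme_id, substrate_id,
        status, source_anchor); substrate ids are resolved to canonical
        keys through the registry."""
        m = cls()
        for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
            cpd = registry[row["substrate_id"]]
            if cpd.key is None:
                raise CascadeError(
                    f"activity substrate {cpd.id} has no skeleton")
            m.set(row["enzyme_id"], cpd.key, row["status"])
        return m

    def to_tsv(self, registry: Optional[CompoundRegistry] = None) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
        w.writerow(["enzyme_id", "substrate_key", "status"])
        for (enz, key), status in sorted(self._facts.items()):
            w.writerow([enz, key, status])
        return buf.getvalue()


def paper_activity_matrix(registry: CompoundRegistry) -> ActivityMatrix:
    """The transcribed activity observations for the IPDO enzymes."""
    text = resources.files("dioldesign.data").joinpath(
        "activities.tsv").read_text()
    return ActivityMatrix.from_tsv(text, registry)


@dataclass
class StepResolution:
    """One resolved step of a route ordering."""

    step: str                                   # H / D / DR
    substrate: Optional[Compound]
    product: Optional[Compound]
    pairs: List[Tuple[str, str]]                # (enzyme id, substrate key)
    reactions: List[Reaction]
    possible: bool                              # chemically replayable
    reason: str = ""

    def describe(self, registry: CompoundRegistry) -> str:
        sub = self.substrate.name if self.substrate else "?"
        return f"{self.step} on {sub}"


@dataclass
class RouteOrdering:
    """One ordering of the three lumped cascade steps with replayed
    intermediates."""

    label: str
    steps: Tuple[str, ...]
    resolutions: List[StepResolution]
    product: Optional[Compound]

    @property
    def chemically_possible(self) -> bool:
        return all(r.possible for r in self.resolutions)

    def reactions(self) -> List[Reaction]:
        out: List[Reaction] = []
        for r in self.resolutions:
            out.extend(r.reactions)
        return out


@dataclass
class FilterVerdict:
    route: RouteOrdering
    feasible: bool
    failing_step: Optional[StepResolution] = None
    failing_reason: str = ""


def _enzyme_for(step: str, spec: CascadeSpec) -> List[str]:
    if step == "H":
        return [spec.hydroxylase or "unassigned"]
    if step == "D":
        return [spec.deaminase or "unassigned"]
    return [spec.decarboxylase or "unassigned",
            spec.reductase or "unassigned"]


def enumerate_orderings(cascade: Pathway,
                        registry: Optional[CompoundRegistry] = None
                        ) -> List[RouteOrdering]:
    """All six orderings of the lumped three-step cascade, each replayed.

    Chemically impossible steps are recorded on the ordering (with the
    failing motif) but the ordering is not removed here; feasibility is
    the business of :func:`filter_routes`.
    """
    registry = registry or CompoundRegistry()
    spec = cascade.provenance
    uid = substrate_position_uid(registry, spec.substrate_id, spec.position)
    out: List[RouteOrdering] = []
    for label, steps in ROUTE_ORDERINGS.items():
        sk = registry[spec.substrate_id].skeleton
        assert sk is not None
        current_cpd: Optional[Compound] = registry[spec.substrate_id]
        resolutions: List[StepResolution] = []
        dead = False
        for step in steps:
            enzymes = _enzyme_for(step, spec)
            if dead or current_cpd is None:
                resolutions.append(StepResolution(
                    step, None, None, [], [], False,
                    "unreachable after an impossible step"))
                continue
            try:
                if step == "H":
                    nxt = apply_hydroxylation(sk, uid)
                    stage = [("H", nxt)]
                elif step == "D":
                    nxt = apply_deamination(sk, spec.deaminase_variant)
                    stage = [("Dd" if spec.deaminase_variant == "dehydrating"
                              else "D", nxt)]
                else:  # DR, two chained sub-reactions
                    mid = apply_decarboxylation(sk)
                    nxt = apply_reduction(mid)
                    stage = [("Dc", mid), ("R", nxt)]
            except CascadeError as exc:
                resolutions.append(StepResolution(
                    step, current_cpd, None,
                    [(e, current_cpd.key or "") for e in enzymes], [],
                    False, str(exc)))
                dead = True
                continue
            pairs: List[Tuple[str, str]] = []
            reactions: List[Reaction] = []
            sub_cpd, sub_sk = current_cpd, sk
            for enzyme, (code, stage_sk) in zip(enzymes, stage):
                prod_cpd = registry.get_or_create(stage_sk)
                pairs.append((enzyme, sub_cpd.key or ""))
                reactions.append(_step_reaction(
                    f"{label}_{len(resolutions)+1}_{code}", sub_cpd,
                    prod_cpd, code, enzyme))
                sub_cpd, sub_sk = prod_cpd, stage_sk
            resolutions.append(StepResolution(
                step, current_cpd, sub_cpd, pairs, reactions, True))
            current_cpd, sk = sub_cpd, sub_sk
        out.append(RouteOrdering(label, steps, resolutions,
                                 current_cpd if not dead else None))
    return out


def filter_routes(orderings: Sequence[RouteOrdering],
                  matrix: ActivityMatrix,
                  policy: str = "strict") -> List[FilterVerdict]:
    """Filter orderings by enzyme-substrate activity.

    ``strict``: an unknown activity fact counts as infeasible;
    ``permissive``: unknown counts as feasible.  A chemically impossible
    step is always infeasible regardless of the matrix.  Returns one
    verdict per ordering, preserving order; eliminated routes carry their
    first failing step.
    """
    if policy not in ("strict", "permissive"):
        raise ValueError(f"policy must be strict or permissive, got {policy!r}")
    allowed = {"active"} if policy == "strict" else {"active", "unknown"}
    verdicts: List[FilterVerdict] = []
    for route in orderings:
        verdict = FilterVerdict(route, True)
        for res in route.resolutions:
            if not res.possible:
                verdict = FilterVerdict(
                    route, False, res,
                    f"chemically impossible: {res.reason}")
                break
            bad = [(e, k) for e, k in res.pairs
                   if matrix.lookup(e, k) not in allowed]
            if bad:
                enz, key = bad[0]
                verdict = FilterVerdict(
                    route, False, res,
                    f"{enz} {matrix.lookup(enz, key)} on substrate of "
                    f"step {res.step}")
                break
        verdicts.append(verdict)
    return verdicts


def feasible_routes(verdicts: Sequence[FilterVerdict]) -> List[RouteOrdering]:
    return [v.route for v in verdicts if v.feasible]


def unlumped_orderings_with_dr_adjacency(n_fixed_steps: int = 2
                                         ) -> List[Tuple[str, ...]]:
    """Orderings of the four unlumped steps {H, D, Dc, R} in which the
    reduction immediately follows the decarboxylation.

    Provided for the lumping argument: these are exactly the six lumped
    orderings with DR expanded in place.
    """
    out = []
    for perm in permutations(("H", "D", "Dc", "R")):
        i, j = perm.index("Dc"), perm.index("R")
        if j == i + 1:
            out.append(perm)
    return out


def make_random_activity_matrix(seed: int, p_active: float,
                                registry: Optional[CompoundRegistry] = None,
                                enzymes: Sequence[str] = ("MFL", "AAD",
                                                          "KDC", "YqhD"),
                                substrate_ids: Sequence[str] = (
                                    "leu", "4ohleu", "kic", "4ohkic",
                                    "mbal", "hmbald", "ipt", "ipdo"),
                                ) -> ActivityMatrix:
    """Reproducible random activity matrix over the IPDO enzyme x
    intermediate grid; each pair is active with probability ``p_active``,
    inactive otherwise (no unknowns)."""
    if not 0 <= p_active <= 1:
        raise ValueError("p_active must be within [0, 1]")
    registry = registry or CompoundRegistry()
    rng = random.Random(seed)
    m = ActivityMatrix()
    for enz in enzymes:
        for sid in substrate_ids:
            key = registry[sid].key
            assert key is not None
            m.set(enz, key,
                  "active" if rng.random() < p_active else "inactive")
    return m
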