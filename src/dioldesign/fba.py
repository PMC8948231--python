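"""Stoichiometric models and LP-based maximum theoretical yield.

A :class:`StoichModel` is a plain steady-state metabolic model: metabolites
(optionally with formula/charge), reactions with flux bounds in
mmol gDCW-1 h-1, and an objective reaction.  Models are read from the
package's native JSON, from BiGG-style JSON or from SBML level-3 FBC
(the latter two through cobrapy), extended with the four-reaction IPDO
pathway, and solved as a linear program (scipy HiGHS): maximise the target
exchange flux subject to S v = 0 and the bounds, with the substrate uptake
fixed ("was set at 15 mmol/g/DCW" is read as fixing both bounds).  The
reported yield is objective flux / substrate uptake (mol/mol).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .chem import ChemError, Compound, Reaction, element_balance


class ModelError(ChemError):
    pass


class ParseError(ModelError):
    """Malformed model file; carries location information when available."""


class MappingError(ModelError):
    """A required metabolite id could not be mapped into the model."""


_DEFAULT_BOUND = 1000.0


@dataclass
class ModelMetabolite:
    id: str
    name: str = ""
    formula: Optional[Dict[str, int]] = None
    charge: Optional[int] = None
    compartment: str = ""


@dataclass
class ModelReaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -_DEFAULT_BOUND
    upper_bound: float = _DEFAULT_BOUND
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} above "
                f"upper bound {self.upper_bound}")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


@dataclass
class StoichModel:
    id: str = "model"
    metabolites: Dict[str, ModelMetabolite] = field(default_factory=dict)
    reactions: Dict[str, ModelReaction] = field(default_factory=dict)
    objective: Optional[str] = None

    # -- construction --------------------------------------------------

    def add_metabolite(self, met: ModelMetabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: ModelReaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelError(
                f"reaction {rxn.id} references unknown metabolites {missing}")
        self.reactions[rxn.id] = rxn

    def copy(self) -> "StoichModel":
        new = StoichModel(id=self.id, objective=self.objective)
        for m in self.metabolites.values():
            new.metabolites[m.id] = ModelMetabolite(
                m.id, m.name, dict(m.formula) if m.formula else None,
                m.charge, m.compartment)
        for r in self.reactions.values():
            new.reactions[r.id] = ModelReaction(
                r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                r.name)
        return new

    def exchanges(self) -> List[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        met_ids = sorted(self.metabolites)
        rxn_ids = sorted(self.reactions)
        S = np.zeros((len(met_ids), len(rxn_ids)))
        mix = {m: i for i, m in enumerate(met_ids)}
        for j, rid in enumerate(rxn_ids):
            for mid, coeff in self.reactions[rid].stoichiometry.items():
                S[mix[mid], j] = coeff
        return S, met_ids, rxn_ids

    # -- native JSON ---------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "dioldesign-model",
            "version": 1,
            "id": self.id,
            "objective": self.objective,
            "metabolites": [
                {"id": m.id, "name": m.name, "formula": m.formula,
                 "charge": m.charge, "compartment": m.compartment}
                for m in sorted(self.metabolites.values(),
                                key=lambda m: m.id)],
            "reactions": [
                {"id": r.id, "name": r.name,
                 "stoichiometry": dict(sorted(r.stoichiometry.items())),
                 "lower_bound": r.lower_bound, "upper_bound": r.upper_bound}
                for r in sorted(self.reactions.values(), key=lambda r: r.id)],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StoichModel":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(
                f"malformed model JSON at line {exc.lineno}, column "
                f"{exc.colno}: {exc.msg}") from None
        if doc.get("format") != "dioldesign-model":
            raise ParseError("not a dioldesign native model file")
        model = cls(id=doc.get("id", "model"),
                    objective=doc.get("objective"))
        for m in doc["metabolites"]:
            model.add_metabolite(ModelMetabolite(
                m["id"], m.get("name", ""), m.get("formula"),
                m.get("charge"), m.get("compartment", "")))
        for r in doc["reactions"]:
            model.add_reaction(ModelReaction(
                r["id"], r["stoichiometry"], r["lower_bound"],
                r["upper_bound"], r.get("name", "")))
        return model

    def balance_report(self) -> Dict[str, str]:
        """Element/charge residual description per unbalanced internal
        reaction (exchanges excluded); empty dict means all balanced."""
        compounds = {}
        for m in self.metabolites.values():
            if m.formula is None:
                return {"*": "model carries no formulas; balance not "
                             "checkable"}
            compounds[m.id] = Compound(
                id=m.id, name=m.name or m.id, formula=m.formula,
                charge=m.charge or 0, role="cofactor")
        out = {}
        for r in self.reactions.values():
            if r.is_exchange:
                continue
            rx = Reaction(id=r.id,
                          stoichiometry={m: Fraction(v).limit_denominator(
                              10 ** 6) for m, v in r.stoichiometry.items()})
            rep = element_balance(rx, compounds)
            if not rep.balanced:
                out[r.id] = str(rep)
        return out


# ---------------------------------------------------------------------------
# readers


def _from_cobra(cm) -> StoichModel:
    model = StoichModel(id=cm.id or "model")
    for m in cm.metabolites:
        formula = None
        if m.formula:
            from .chem import _parse_formula
            formula = _parse_formula(m.formula)
        model.add_metabolite(ModelMetabolite(
            m.id, m.name or "", formula, m.charge, m.compartment or ""))
    for r in cm.reactions:
        model.add_reaction(ModelReaction(
            r.id, {m.id: coeff for m, coeff in r.metabolites.items()},
            float(r.lower_bound), float(r.upper_bound), r.name or ""))
    try:
        objective = {v.name for v in cm.objective.variables}
        fwd = [r.id for r in cm.reactions if r.id in objective]
        model.objective = fwd[0] if fwd else None
    except Exception:
        model.objective = None
    return model


def read_model(source) -> StoichModel:
    """Read a model from a path: native JSON, BiGG-style JSON or SBML-FBC.

    The format is sniffed from the content.  Malformed files raise
    :class:`ParseError` (with a location for JSON); no partial model is
    ever returned.  A BiGG/SBML model without an objective loads with
    ``objective=None``; solving then requires an explicit target.
    """
    import pathlib
    path = pathlib.Path(source)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("<"):
        import cobra
        try:
            return _from_cobra(cobra.io.read_sbml_model(str(path)))
        except Exception as exc:
            raise ParseError(f"SBML read failed: {exc}") from None
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"malformed JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}") from None
    if doc.get("format") == "dioldesign-model":
        return StoichModel.from_json(text)
    if "metabolites" in doc and "reactions" in doc:
        import cobra
        try:
            return _from_cobra(cobra.io.load_json_model(str(path)))
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"BiGG JSON read failed: {exc}") from None
    raise ParseError("unrecognised model format")


def write_model(model: StoichModel, path) -> None:
    import pathlib
    pathlib.Path(path).write_text(model.to_json())


# ---------------------------------------------------------------------------
# IPDO pathway extension


#: metabolite id maps per model dialect; keys are the pathway-internal
#: names, values the model ids
NATIVE_ID_MAP = {k: k for k in ("leu", "akg", "succ", "o2", "co2", "nh4",
                                "nadph", "nadp", "h")}
BIGG_ID_MAP = {"leu": "leu__L_c", "akg": "akg_c", "succ": "succ_c",
               "o2": "o2_c", "co2": "co2_c", "nh4": "nh4_c",
               "nadph": "nadph_c", "nadp": "nadp_c", "h": "h_c"}

#: formulas/charges of the four new species (pH-7 majority forms)
_IPDO_SPECIES = {
    "4ohleu": ("4-hydroxy-leucine", {"C": 6, "H": 13, "N": 1, "O": 3}, 0),
    "4ohkic": ("4-hydroxy-4-methyl-2-oxopentanoate",
               {"C": 6, "H": 9, "O": 4}, -1),
    "hmbald": ("3-hydroxy-3-methylbutanal", {"C": 5, "H": 10, "O": 2}, 0),
    "ipdo": ("isopentyldiol", {"C": 5, "H": 12, "O": 2}, 0),
}


def _pick_id_map(model: StoichModel,
                 id_map: Optional[Mapping[str, str]]) -> Mapping[str, str]:
    if id_map is not None:
        return id_map
    for candidate in (NATIVE_ID_MAP, BIGG_ID_MAP):
        if all(v in model.metabolites for v in candidate.values()):
            return candidate
    missing = [v for v in BIGG_ID_MAP.values() if v not in model.metabolites]
    raise MappingError(
        "model matches neither the native nor the BiGG id dialect; "
        f"missing (BiGG guess): {missing}; pass an explicit id_map")


def add_ipdo_pathway(model: StoichModel,
                     id_map: Optional[Mapping[str, str]] = None,
                     printed_forms: bool = False) -> StoichModel:
    """Return a copy of the model extended with the IPDO pathway.

    Adds the four cascade reactions (leucine hydroxylation, oxidative
    deamination, decarboxylation, NADPH reduction) plus an IPDO exchange:
    five reactions and four metabolites.  By default the reactions are the
    fully H+/charge-balanced pH-7 forms; ``printed_forms`` installs the
    reactions exactly as conventionally printed (no explicit H+), which
    leaves reactions 3 and 4 intentionally unbalanced for audit purposes.

    Raises :class:`MappingError` naming the missing species if the model's
    dialect cannot be resolved, and :class:`ModelError` if the pathway was
    already added (duplicate ids).
    """
    mp = dict(_pick_id_map(model, id_map))
    new = model.copy()
    leu = new.metabolites[mp["leu"]]
    compartment = leu.compartment
    suffix = "_c" if mp["leu"].endswith("_c") else ""
    for short, (name, formula, charge) in _IPDO_SPECIES.items():
        mid = short + suffix
        mp[short] = mid
        new.add_metabolite(ModelMetabolite(mid, name, dict(formula), charge,
                                           compartment))
    half = 0.5
    balanced = {
        "IPDO_HYDROX": ({"leu": -1, "akg": -1, "o2": -1,
                         "4ohleu": 1, "succ": 1, "co2": 1},
                        "leucine 4-hydroxylase (MFL)"),
        "IPDO_DEAM": ({"4ohleu": -1, "o2": -half, "4ohkic": 1, "nh4": 1},
                      "L-amino acid deaminase (AAD) on 4OH-Leu"),
        "IPDO_DECARB": ({"4ohkic": -1, "h": -1, "hmbald": 1, "co2": 1},
                        "2-keto acid decarboxylase (KDC)"),
        "IPDO_RED": ({"hmbald": -1, "nadph": -1, "h": -1,
                      "ipdo": 1, "nadp": 1},
                     "aldehyde reductase (YqhD)"),
    }
    if printed_forms:
        balanced["IPDO_DECARB"] = (
            {"4ohkic": -1, "hmbald": 1, "co2": 1}, balanced["IPDO_DECARB"][1])
        balanced["IPDO_RED"] = (
            {"hmbald": -1, "nadph": -1, "h": -1, "ipdo": 1, "nadp": 1},
            balanced["IPDO_RED"][1])
    for rid, (stoich, name) in balanced.items():
        new.add_reaction(ModelReaction(
            rid, {mp[m]: c for m, c in stoich.items()}, 0.0, _DEFAULT_BOUND,
            name))
    new.add_reaction(ModelReaction("EX_ipdo", {mp["ipdo"]: -1.0},
                                   0.0, _DEFAULT_BOUND, "IPDO exchange"))
    return new


# ---------------------------------------------------------------------------
# LP yield


@dataclass
class FluxResult:
    """Outcome of a maximum-yield LP.

    ``yield_mol_mol`` is objective flux / substrate uptake and is reported
    only for an optimal solve with positive uptake.
    """

    status: str                       # optimal | infeasible | unbounded
    objective_flux: Optional[float] = None
    substrate_uptake: Optional[float] = None
    yield_mol_mol: Optional[float] = None
    fluxes: Optional[Dict[str, float]] = None

    def to_dict(self) -> Dict:
        return {"status": self.status, "objective_flux": self.objective_flux,
                "substrate_uptake": self.substrate_uptake,
                "yield_mol_mol": self.yield_mol_mol}


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible",
           3: "unbounded", 4: "numerical trouble"}


def max_yield(model: StoichModel, target_exchange: str,
              substrate_exchange: str = "EX_glc",
              substrate_rate: float = 15.0,
              with_fluxes: bool = False) -> FluxResult:
    """Maximum theoretical yield of the target on the substrate.

    The substrate exchange is *fixed* at an uptake of ``substrate_rate``
    (both bounds set to -rate, mmol gDCW-1 h-1); all other bounds are used
    as given.  Returns the LP status verbatim -- infeasible or unbounded
    results are reported, never coerced.
    """
    if substrate_rate <= 0:
        raise ValueError("substrate_rate must be positive")
    for rid in (target_exchange, substrate_exchange):
        if rid not in model.reactions:
            raise ModelError(f"no reaction {rid!r} in model {model.id}")
    solve = model.copy()
    ex = solve.reactions[substrate_exchange]
    ex.lower_bound = ex.upper_bound = -abs(substrate_rate)
    S, met_ids, rxn_ids = solve.stoichiometric_matrix()
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(target_exchange)] = -1.0
    bounds = [(solve.reactions[r].lower_bound,
               solve.reactions[r].upper_bound) for r in rxn_ids]
    res = linprog(c, A_eq=S, b_eq=np.zeros(len(met_ids)), bounds=bounds,
                  method="highs")
    status = _STATUS.get(res.status, f"solver status {res.status}")
    if status != "optimal":
        return FluxResult(status=status)
    obj = float(-res.fun)
    fluxes = (dict(zip(rxn_ids, (float(v) for v in res.x)))
              if with_fluxes else None)
    return FluxResult(status="optimal", objective_flux=obj,
                      substrate_uptake=abs(substrate_rate),
                      yield_mol_mol=obj / abs(substrate_rate),
                      fluxes=fluxes)
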