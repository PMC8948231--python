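"""Synthetic inputs: a balanced core E. coli model, random activity
matrices and perturbed thermodynamic tables.

The core model is a hand-curated, programmatically generated network --
not a random graph -- because the FBA properties (exact LP optima, carbon
bounds, relaxation monotonicity) need a known-good, mass- and
charge-balanced backbone.  It covers lumped glycolysis, pyruvate
dehydrogenase, the TCA cycle, anaplerosis, glutamate amination, the
acetolactate route to 2-ketoisocaproate and leucine (AlsS/IlvCD/LeuABCD
lumped, as in the engineered production strains), oxidative
phosphorylation at P/O = 2, transhydrogenase, optional oxidative pentose
phosphate cycling for NADPH, ATP maintenance, and exchanges for glucose,
O2, ammonium, phosphate, sulfate, CO2, water, protons and secreted
leucine.  Every internal reaction is element- and charge-balanced in the
pH-7 majority species (checkable via ``StoichModel.balance_report``).

Randomness is confined to the activity matrices and thermo-table
perturbations; every artifact is regenerable bit-identically from
(params, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, Optional

from .chem import cofactor_compounds
from .fba import ModelMetabolite, ModelReaction, StoichModel
from .routes import make_random_activity_matrix  # re-export (module surface)
from .thermo import GroupTable

__all__ = ["CoreModelParams", "make_core_model",
           "make_random_activity_matrix", "perturb_thermo_table"]


@dataclass
class CoreModelParams:
    """Knobs of the core-model generator.

    ``atp_maintenance`` (mmol gDCW-1 h-1) is the lower bound forced
    through the ATP hydrolysis reaction; the default is 0 (no
    non-growth-associated maintenance) and any effect of a nonzero value
    on yields is meant to be reported, not hidden.
    """

    include_ppp: bool = True
    include_tca: bool = True
    atp_maintenance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atp_maintenance < 0:
            raise ValueError("atp_maintenance must be >= 0")


#: metabolites beyond the shared cofactor set (formula, charge)
_EXTRA_METS = {
    "cit": ("citrate", {"C": 6, "H": 5, "O": 7}, -3),
    "icit": ("isocitrate", {"C": 6, "H": 5, "O": 7}, -3),
    "fum": ("fumarate", {"C": 4, "H": 2, "O": 4}, -2),
    "mal": ("L-malate", {"C": 4, "H": 4, "O": 5}, -2),
    "oaa": ("oxaloacetate", {"C": 4, "H": 2, "O": 5}, -2),
    "alac": ("2-acetolactate", {"C": 5, "H": 7, "O": 4}, -1),
    "kiv": ("2-ketoisovalerate", {"C": 5, "H": 7, "O": 3}, -1),
    "kic": ("2-ketoisocaproate", {"C": 6, "H": 9, "O": 3}, -1),
    "leu": ("L-leucine", {"C": 6, "H": 13, "N": 1, "O": 2}, 0),
    "so4": ("sulfate", {"O": 4, "S": 1}, -2),
}

#: (id, name, stoichiometry, lb, ub); None bounds mean the default
_CORE_REACTIONS = [
    ("GLYC", "glycolysis (lumped)",
     {"glc": -1, "adp": -2, "pi": -2, "nad": -2,
      "pyr": 2, "atp": 2, "nadh": 2, "h2o": 2, "h": 2}, 0, 1000),
    ("PDH", "pyruvate dehydrogenase",
     {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1},
     0, 1000),
    ("CS", "citrate synthase",
     {"accoa": -1, "h2o": -1, "oaa": -1, "cit": 1, "coa": 1, "h": 1},
     0, 1000),
    ("ACONT", "aconitase", {"cit": -1, "icit": 1}, -1000, 1000),
    ("ICDH", "isocitrate dehydrogenase (NADP)",
     {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1}, 0, 1000),
    ("AKGDH", "2-oxoglutarate dehydrogenase",
     {"akg": -1, "coa": -1, "nad": -1, "succoa": 1, "co2": 1, "nadh": 1},
     0, 1000),
    ("SUCOAS", "succinyl-CoA synthetase",
     {"succoa": -1, "adp": -1, "pi": -1, "succ": 1, "atp": 1, "coa": 1},
     -1000, 1000),
    ("SUCD", "succinate dehydrogenase (to ubiquinone pool, lumped to O2)",
     {"succ": -1, "o2": -0.5, "fum": 1, "h2o": 1}, 0, 1000),
    ("FUM", "fumarase", {"fum": -1, "h2o": -1, "mal": 1}, -1000, 1000),
    ("MDH", "malate dehydrogenase",
     {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1, "h": 1}, -1000, 1000),
    ("PC", "anaplerotic carboxylation (lumped)",
     {"pyr": -1, "co2": -1, "atp": -1, "h2o": -1,
      "oaa": 1, "adp": 1, "pi": 1, "h": 2}, 0, 1000),
    ("GDH", "glutamate dehydrogenase (NADPH)",
     {"akg": -1, "nh4": -1, "nadph": -1, "h": -1,
      "glu": 1, "nadp": 1, "h2o": 1}, 0, 1000),
    ("ALS", "acetolactate synthase (AlsS)",
     {"pyr": -2, "h": -1, "alac": 1, "co2": 1}, 0, 1000),
    ("ILVCD", "ketol-acid reductoisomerase + dehydratase (IlvCD, lumped)",
     {"alac": -1, "nadph": -1, "h": -1, "kiv": 1, "nadp": 1, "h2o": 1},
     0, 1000),
    ("LEUABCD", "2-isopropylmalate route KIV -> KIC (LeuABCD, lumped)",
     {"kiv": -1, "accoa": -1, "h2o": -1, "nad": -1,
      "kic": 1, "coa": 1, "co2": 1, "nadh": 1, "h": 1}, 0, 1000),
    ("ILVE", "branched-chain aminotransferase",
     {"kic": -1, "glu": -1, "leu": 1, "akg": 1}, -1000, 1000),
    ("OXPHOS", "NADH oxidation + ATP synthase, P/O = 2 (lumped)",
     {"nadh": -1, "o2": -0.5, "adp": -2, "pi": -2, "h": -3,
      "nad": 1, "atp": 2, "h2o": 3}, 0, 1000),
    ("THD", "transhydrogenase (PntAB/UdhA, lumped)",
     {"nadh": -1, "nadp": -1, "nad": 1, "nadph": 1}, -1000, 1000),
    ("ATPM", "ATP maintenance", {"atp": -1, "h2o": -1,
                                 "adp": 1, "pi": 1, "h": 1}, 0, 1000),
]

_PPP_REACTION = (
    "PPPOX", "oxidative pentose phosphate cycling (lumped NADPH supply)",
    {"glc": -1, "nadp": -12, "h2o": -6, "co2": 6, "nadph": 12, "h": 12},
    0, 1000)

_TCA_IDS = {"CS", "ACONT", "ICDH", "AKGDH", "SUCOAS", "SUCD", "FUM", "MDH"}

_EXCHANGES = [
    ("EX_glc", "glc", -10, 0),
    ("EX_o2", "o2", -1000, 0),
    ("EX_nh4", "nh4", -1000, 0),
    ("EX_pi", "pi", -1000, 0),
    ("EX_so4", "so4", -1000, 0),
    ("EX_co2", "co2", 0, 1000),
    ("EX_h2o", "h2o", -1000, 1000),
    ("EX_h", "h", -1000, 1000),
    ("EX_leu", "leu", 0, 1000),
]


def make_core_model(params: Optional[CoreModelParams] = None) -> StoichModel:
    """Build the core model; deterministic for given params."""
    params = params or CoreModelParams()
    model = StoichModel(id="dioldesign_core")
    shared = cofactor_compounds()
    used = set()
    for _, _, stoich, _, _ in _CORE_REACTIONS + [_PPP_REACTION]:
        used.update(stoich)
    used.update(m for _, m, _, _ in _EXCHANGES)
    for mid in sorted(used):
        if mid in _EXTRA_METS:
            name, formula, charge = _EXTRA_METS[mid]
        elif mid in shared:
            c = shared[mid]
            name, formula, charge = c.name, c.formula, c.charge
        else:
            raise KeyError(f"no formula for metabolite {mid}")
        model.add_metabolite(ModelMetabolite(mid, name, dict(formula),
                                             charge, "c"))
    for rid, name, stoich, lb, ub in _CORE_REACTIONS:
        if not params.include_tca and rid in _TCA_IDS:
            continue
        model.add_reaction(ModelReaction(rid, dict(stoich), lb, ub, name))
    if params.include_ppp:
        rid, name, stoich, lb, ub = _PPP_REACTION
        model.add_reaction(ModelReaction(rid, dict(stoich), lb, ub, name))
    if params.atp_maintenance > 0:
        model.reactions["ATPM"].lower_bound = params.atp_maintenance
    for rid, mid, lb, ub in _EXCHANGES:
        model.add_reaction(ModelReaction(rid, {mid: -1.0}, lb, ub,
                                         f"{mid} exchange"))
    model.objective = "EX_leu"
    bad = model.balance_report()
    if bad:
        raise AssertionError(f"core model unbalanced: {bad}")
    return model


def perturb_thermo_table(table: GroupTable, sigma: float,
                         seed: int) -> GroupTable:
    """Add zero-mean Gaussian noise (kJ/mol) to the group contributions.

    Overrides and interaction corrections are left untouched; sigma = 0
    returns an identical table.  Reproducible for a given seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = random.Random(seed)
    groups = {g: v + (rng.gauss(0.0, sigma) if sigma else 0.0)
              for g, v in sorted(table.groups.items())}
    version = (table.version if sigma == 0
               else f"{table.version}+noise(sigma={sigma},seed={seed})")
    return GroupTable(version=version, origin=table.origin, groups=groups,
                      corrections=dict(table.corrections),
                      overrides=dict(table.overrides))
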