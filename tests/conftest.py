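"""Shared fixtures and the exact rational-arithmetic LP oracle."""

from __future__ import annotations

from fractions import Fraction
from typing import Dict, List, Optional, Tuple

import pytest

from dioldesign import (CompoundRegistry, GroupTable, ThermoConditions,
                        build_cascade, default_config, enumerate_orderings,
                        make_core_model)


@pytest.fixture()
def registry() -> CompoundRegistry:
    return CompoundRegistry()


@pytest.fixture()
def ipdo_spec():
    return next(s for s in default_config()
                if s.substrate_id == "leu" and s.position == "C4")


@pytest.fixture()
def ipdo_pathway(registry, ipdo_spec):
    return build_cascade(ipdo_spec, registry)


@pytest.fixture()
def ipdo_orderings(registry, ipdo_pathway):
    return {o.label: o for o in enumerate_orderings(ipdo_pathway, registry)}


@pytest.fixture(scope="session")
def group_table() -> GroupTable:
    return GroupTable.load()


@pytest.fixture()
def conditions() -> ThermoConditions:
    return ThermoConditions()


@pytest.fixture()
def core_model():
    return make_core_model()


# ---------------------------------------------------------------------------
# exact LP oracle: two-phase full-tableau simplex over Fractions, with
# Bland's rule.  Deliberately independent of the scipy-based solver in the
# package: dense tableau, no scaling, exact arithmetic.


def _simplex_phase(T: List[List[Fraction]], basis: List[int],
                   n_cols: int) -> None:
    """Minimise the last row of tableau T in place (Bland's rule)."""
    m = len(T) - 1
    while True:
        cost = T[-1]
        enter = next((j for j in range(n_cols) if cost[j] < 0), None)
        if enter is None:
            return
        ratios = [(T[i][-1] / T[i][enter], basis[i], i)
                  for i in range(m) if T[i][enter] > 0]
        if not ratios:
            raise ArithmeticError("LP is unbounded")
        _, _, leave = min(ratios)
        piv = T[leave][enter]
        T[leave] = [v / piv for v in T[leave]]
        for i in range(len(T)):
            if i != leave and T[i][enter] != 0:
                f = T[i][enter]
                T[i] = [a - f * b for a, b in zip(T[i], T[leave])]
        basis[leave] = enter


def exact_max_flux(model, target: str) -> Fraction:
    """Exact maximum flux through ``target`` subject to S v = 0 and the
    model bounds, by rational two-phase simplex.

    Bounds must be finite.  Raises ArithmeticError("infeasible") /
    ("unbounded") accordingly.
    """
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.metabolites)
    n, m_eq = len(rxn_ids), len(met_ids)
    lo = [Fraction(model.reactions[r].lower_bound) for r in rxn_ids]
    hi = [Fraction(model.reactions[r].upper_bound) for r in rxn_ids]
    cap = [h - l for l, h in zip(lo, hi)]
    if any(c < 0 for c in cap):
        raise ArithmeticError("infeasible")
    # S x = -S lo  with x = v - lo, plus x_j + s_j = cap_j
    S: List[List[Fraction]] = [[Fraction(0)] * n for _ in range(m_eq)]
    mix = {mid: i for i, mid in enumerate(met_ids)}
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[mix[mid]][j] = Fraction(coeff).limit_denominator(10 ** 9)
    b_eq = [-sum(S[i][j] * lo[j] for j in range(n)) for i in range(m_eq)]
    # column layout: x (n) | slack (n) | artificial (m_eq) | rhs
    n_struct = 2 * n
    n_cols = n_struct + m_eq
    T: List[List[Fraction]] = []
    basis: List[int] = []
    for i in range(m_eq):
        row = list(S[i]) + [Fraction(0)] * n + [Fraction(0)] * m_eq
        rhs = b_eq[i]
        if rhs < 0:
            row = [-v for v in row]
            rhs = -rhs
        row[n_struct + i] = Fraction(1)
        T.append(row + [rhs])
        basis.append(n_struct + i)
    for j in range(n):
        row = [Fraction(0)] * (n_cols + 1)
        row[j] = Fraction(1)
        row[n + j] = Fraction(1)
        row[-1] = cap[j]
        T.append(row)
        basis.append(n + j)
    # phase 1: minimise sum of artificials
    cost = [Fraction(0)] * (n_cols + 1)
    for j in range(n_struct, n_cols):
        cost[j] = Fraction(1)
    T.append(cost)
    for i in range(m_eq):          # make reduced costs of basis zero
        T[-1] = [a - b for a, b in zip(T[-1], T[i])]
    _simplex_phase(T, basis, n_cols)
    if -T[-1][-1] != 0:
        raise ArithmeticError("infeasible")
    T.pop()
    # pivot any artificial still in the basis out (or drop its row)
    for i in reversed(range(len(basis))):
        if basis[i] >= n_struct:
            enter = next((j for j in range(n_struct) if T[i][j] != 0), None)
            if enter is None:
                T.pop(i)
                basis.pop(i)
                continue
            piv = T[i][enter]
            T[i] = [v / piv for v in T[i]]
            for k in range(len(T)):
                if k != i and T[k][enter] != 0:
                    f = T[k][enter]
                    T[k] = [a - f * b for a, b in zip(T[k], T[i])]
            basis[i] = enter
    # phase 2: minimise -x_target
    tgt = rxn_ids.index(target)
    cost = [Fraction(0)] * (n_cols + 1)
    cost[tgt] = Fraction(-1)
    T.append(cost)
    for i, bj in enumerate(basis):
        if bj == tgt:
            T[-1] = [a + b for a, b in zip(T[-1], T[i])]
    # artificial columns are excluded from phase 2
    _simplex_phase(T, basis, n_struct)
    x_tgt = Fraction(0)
    for i, bj in enumerate(basis):
        if bj == tgt:
            x_tgt = T[i][-1]
    return x_tgt + lo[tgt]


@pytest.fixture(scope="session")
def rational_lp():
    return exact_max_flux
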