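"""Model I/O, IPDO pathway extension and LP yield computation."""

import json
import random

import numpy as np
import pytest

from dioldesign import (StoichModel, add_ipdo_pathway, make_core_model,
                        max_yield, read_model, write_model)
from dioldesign.fba import (MappingError, ModelError, ModelMetabolite,
                            ModelReaction, ParseError, BIGG_ID_MAP)
from dioldesign.synthetic import CoreModelParams


@pytest.fixture()
def ipdo_model(core_model):
    return add_ipdo_pathway(core_model)


class TestModelIO:
    def test_native_round_trip_is_identity(self, tmp_path, core_model):
        p = tmp_path / "core.json"
        write_model(core_model, p)
        back = read_model(p)
        assert back.to_json() == core_model.to_json()
        assert len(back.metabolites) == len(core_model.metabolites)
        assert len(back.reactions) == len(core_model.reactions)

    def test_bigg_json_read_counts_match_file(self, tmp_path):
        """A BiGG-style JSON file loads through the cobra-backed reader
        with metabolite/reaction counts taken from the file itself."""
        doc = {
            "id": "mini",
            "metabolites": [
                {"id": "glc__D_e", "name": "glucose", "compartment": "e",
                 "formula": "C6H12O6", "charge": 0},
                {"id": "glc__D_c", "name": "glucose", "compartment": "c",
                 "formula": "C6H12O6", "charge": 0},
            ],
            "reactions": [
                {"id": "EX_glc__D_e", "name": "glc exchange",
                 "metabolites": {"glc__D_e": -1.0},
                 "lower_bound": -10.0, "upper_bound": 0.0,
                 "gene_reaction_rule": ""},
                {"id": "GLCt", "name": "transport",
                 "metabolites": {"glc__D_e": -1.0, "glc__D_c": 1.0},
                 "lower_bound": 0.0, "upper_bound": 1000.0,
                 "gene_reaction_rule": ""},
                {"id": "DM_glc__D_c", "name": "demand",
                 "metabolites": {"glc__D_c": -1.0},
                 "lower_bound": 0.0, "upper_bound": 1000.0,
                 "gene_reaction_rule": "", "objective_coefficient": 1.0},
            ],
            "genes": [], "compartments": {"c": "cytosol", "e": "extra"},
            "version": "1",
        }
        p = tmp_path / "mini_bigg.json"
        p.write_text(json.dumps(doc))
        model = read_model(p)
        assert len(model.metabolites) == len(doc["metabolites"])
        assert len(model.reactions) == len(doc["reactions"])
        assert model.reactions["EX_glc__D_e"].lower_bound == -10.0
        r = max_yield(model, "DM_glc__D_c", "EX_glc__D_e", 5.0)
        assert r.yield_mol_mol == pytest.approx(1.0)

    def test_sbml_fbc_round_trip_through_cobra(self, tmp_path, core_model):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("core")
        mets = {mid: cobra.Metabolite(mid, compartment="c")
                for mid in core_model.metabolites}
        for rid, rxn in core_model.reactions.items():
            cr = cobra.Reaction(rid)
            cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
            cm.add_reactions([cr])
            cr.add_metabolites({mets[m]: c
                                for m, c in rxn.stoichiometry.items()})
        p = tmp_path / "core.xml"
        cobra.io.write_sbml_model(cm, str(p))
        back = read_model(p)
        assert set(back.reactions) == set(core_model.reactions)
        for rid in back.reactions:
            assert back.reactions[rid].stoichiometry == \
                core_model.reactions[rid].stoichiometry

    def test_truncated_file_is_parse_error_with_location(self, tmp_path,
                                                         core_model):
        p = tmp_path / "broken.json"
        p.write_text(core_model.to_json()[:200])
        with pytest.raises(ParseError, match="line"):
            read_model(p)

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ModelError):
            ModelReaction("bad", {}, 5.0, -5.0)


class TestAddIpdoPathway:
    def test_adds_five_reactions_four_metabolites(self, core_model,
                                                  ipdo_model):
        assert len(ipdo_model.reactions) == len(core_model.reactions) + 5
        assert len(ipdo_model.metabolites) == len(core_model.metabolites) + 4
        assert "EX_ipdo" in ipdo_model.reactions

    def test_added_reactions_balance(self, ipdo_model):
        assert ipdo_model.balance_report() == {}

    def test_printed_forms_flagged_unbalanced(self, core_model):
        audit = add_ipdo_pathway(core_model, printed_forms=True)
        bad = audit.balance_report()
        assert "IPDO_DECARB" in bad          # printed form omits H+

    def test_adding_twice_is_an_error(self, ipdo_model):
        with pytest.raises(ModelError, match="duplicate"):
            add_ipdo_pathway(ipdo_model)

    def test_unmapped_metabolite_named_in_error(self):
        tiny = StoichModel()
        tiny.add_metabolite(ModelMetabolite("leu", formula={"C": 6}))
        with pytest.raises(MappingError, match="akg"):
            add_ipdo_pathway(tiny)

    def test_bigg_dialect_mapping(self, core_model):
        renamed = StoichModel(id="bigg_like")
        rename = {v: k for k, v in BIGG_ID_MAP.items()}
        for mid, met in core_model.metabolites.items():
            new_id = {k: v for k, v in BIGG_ID_MAP.items()}.get(mid, mid)
            renamed.add_metabolite(ModelMetabolite(
                new_id, met.name, met.formula, met.charge, "c"))
        for rid, rxn in core_model.reactions.items():
            renamed.add_reaction(ModelReaction(
                rid, {BIGG_ID_MAP.get(m, m): c
                      for m, c in rxn.stoichiometry.items()},
                rxn.lower_bound, rxn.upper_bound))
        ext = add_ipdo_pathway(renamed)
        assert "ipdo_c" in ext.metabolites
        r = max_yield(ext, "EX_ipdo", "EX_glc", 15.0)
        assert r.yield_mol_mol > 0


class TestMaxYield:
    def test_core_fixture_yield_matches_exact_lp_oracle(self, ipdo_model,
                                                        rational_lp):
        got = max_yield(ipdo_model, "EX_ipdo", "EX_glc", 15.0)
        assert got.status == "optimal"
        fixed = ipdo_model.copy()
        ex = fixed.reactions["EX_glc"]
        ex.lower_bound = ex.upper_bound = -15.0
        exact = rational_lp(fixed, "EX_ipdo")
        assert got.objective_flux == pytest.approx(float(exact), rel=1e-9)

    def test_deleting_hydroxylase_kills_yield(self, ipdo_model):
        broken = ipdo_model.copy()
        del broken.reactions["IPDO_HYDROX"]
        r = max_yield(broken, "EX_ipdo", "EX_glc", 15.0)
        assert r.status == "optimal"
        assert abs(r.yield_mol_mol) < 1e-9

    def test_carbon_bound_respected(self, ipdo_model):
        """IPDO has 5 carbons against glucose's 6: yield can never exceed
        6/5 = 1.2 mol/mol on a carbon-balanced model."""
        r = max_yield(ipdo_model, "EX_ipdo", "EX_glc", 15.0)
        assert 0 < r.yield_mol_mol <= 1.2

    def test_optimum_invariant_under_reaction_permutation(self, ipdo_model):
        base = max_yield(ipdo_model, "EX_ipdo", "EX_glc", 15.0)
        for seed in range(3):
            rng = random.Random(seed)
            ids = list(ipdo_model.reactions)
            rng.shuffle(ids)
            shuffled = StoichModel(id="perm")
            for met in ipdo_model.metabolites.values():
                shuffled.add_metabolite(met)
            for rid in ids:
                shuffled.add_reaction(ipdo_model.reactions[rid])
            r = max_yield(shuffled, "EX_ipdo", "EX_glc", 15.0)
            assert r.objective_flux == pytest.approx(
                base.objective_flux, rel=1e-6)

    def test_relaxing_bounds_never_decreases_yield(self, ipdo_model):
        base = max_yield(ipdo_model, "EX_ipdo", "EX_glc", 15.0)
        for rid in ("EX_o2", "OXPHOS", "THD", "ILVE", "IPDO_HYDROX"):
            relaxed = ipdo_model.copy()
            rxn = relaxed.reactions[rid]
            rxn.lower_bound = min(rxn.lower_bound, -2000.0) \
                if rxn.lower_bound < 0 else rxn.lower_bound
            rxn.upper_bound = max(rxn.upper_bound, 2000.0)
            r = max_yield(relaxed, "EX_ipdo", "EX_glc", 15.0)
            assert r.yield_mol_mol >= base.yield_mol_mol - 1e-9

    def test_atp_maintenance_effect_is_reported(self):
        lo = add_ipdo_pathway(make_core_model(CoreModelParams(
            atp_maintenance=0.0)))
        hi = add_ipdo_pathway(make_core_model(CoreModelParams(
            atp_maintenance=20.0)))
        y0 = max_yield(lo, "EX_ipdo", "EX_glc", 15.0).yield_mol_mol
        y1 = max_yield(hi, "EX_ipdo", "EX_glc", 15.0).yield_mol_mol
        assert y1 <= y0 + 1e-9        # maintenance can only tax the yield

    def test_infeasible_reported_not_coerced(self, ipdo_model):
        stuck = ipdo_model.copy()
        ex = stuck.reactions["EX_so4"]   # sulfate has no consumer
        ex.lower_bound = ex.upper_bound = -5.0
        r = max_yield(stuck, "EX_ipdo", "EX_glc", 15.0)
        assert r.status == "infeasible"
        assert r.yield_mol_mol is None

    def test_unbounded_reported(self):
        m = StoichModel()
        m.add_metabolite(ModelMetabolite("a"))
        m.add_metabolite(ModelMetabolite("s"))
        m.add_reaction(ModelReaction("EX_s", {"s": -1.0}, -10.0, 0.0))
        m.add_reaction(ModelReaction("SPIN", {"a": 1.0, "s": -1.0},
                                     0.0, np.inf))
        m.add_reaction(ModelReaction("BACK", {"a": -1.0, "s": 1.0},
                                     0.0, np.inf))
        m.add_reaction(ModelReaction("EX_a", {"a": -1.0}, 0.0, np.inf))
        r = max_yield(m, "SPIN", "EX_s", 1.0)
        assert r.status == "unbounded"

    def test_substrate_rate_must_be_positive(self, ipdo_model):
        with pytest.raises(ValueError):
            max_yield(ipdo_model, "EX_ipdo", "EX_glc", 0.0)


class TestCobraCrossCheck:
    def test_scipy_and_cobra_glpk_agree_on_core_ipdo_yield(self, ipdo_model):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("x")
        mets = {mid: cobra.Metabolite(mid, compartment="c")
                for mid in ipdo_model.metabolites}
        for rid, rxn in ipdo_model.reactions.items():
            cr = cobra.Reaction(rid)
            lb, ub = rxn.lower_bound, rxn.upper_bound
            if rid == "EX_glc":
                lb = ub = -15.0
            cr.lower_bound, cr.upper_bound = lb, ub
            cm.add_reactions([cr])
            cr.add_metabolites({mets[m]: c
                                for m, c in rxn.stoichiometry.items()})
        cm.objective = "EX_ipdo"
        sol = cm.optimize()
        ours = max_yield(ipdo_model, "EX_ipdo", "EX_glc", 15.0)
        assert ours.objective_flux == pytest.approx(sol.objective_value,
                                                    rel=1e-6)
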