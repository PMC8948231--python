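"""Group-contribution energies, route profiles and route comparison."""

import math

import pytest

from dioldesign import (GroupTable, Reaction, ThermoConditions, ThermoProfile,
                        cascade_profile, compare_routes, estimate_dfg,
                        perturb_thermo_table, reaction_drg)
from dioldesign.thermo import (ConsistencyError, CoverageError, KJ_PER_KCAL,
                               ProfileStep, decompose)


class TestEstimateDfg:
    def test_group_additivity_of_ethanol_like_skeleton(self, registry,
                                                       group_table):
        """dGf' of a skeleton equals origin + sum of its groups."""
        from dioldesign import skeleton_from_structure
        from dioldesign.chem import Compound
        eth = Compound.from_skeleton(
            "x_eth", "ethanol-like", skeleton_from_structure("C2;OH@1"))
        expected = (group_table.origin + group_table.groups["C_H2"]
                    + group_table.groups["C_H3"]
                    + group_table.groups["hydroxyl"])
        assert estimate_dfg(eth, group_table) == pytest.approx(expected)

    def test_hydroxylation_increment_is_the_group_difference(self, registry,
                                                             group_table):
        """dGf'(4OH-Leu) - dGf'(Leu) equals the C_H1 -> C_H0 + hydroxyl
        replacement implied by the table (pure group additivity)."""
        diff = (estimate_dfg(registry["4ohleu"], group_table)
                - estimate_dfg(registry["leu"], group_table))
        implied = (group_table.groups["C_H0"]
                   + group_table.groups["hydroxyl"]
                   - group_table.groups["C_H1"])
        assert diff == pytest.approx(implied, abs=1e-9)

    def test_override_takes_precedence(self, registry, group_table):
        assert estimate_dfg(registry["akg"], group_table) == \
            group_table.overrides["akg"]

    def test_uncoverable_compound_reports_missing_groups(self, registry,
                                                         group_table):
        table = GroupTable(version="crippled", origin=0.0,
                           groups={k: v for k, v in group_table.groups.items()
                                   if k != "hydroxyl"},
                           corrections=dict(group_table.corrections),
                           overrides={})
        with pytest.raises(CoverageError, match="hydroxyl"):
            estimate_dfg(registry["4ohleu"], table)

    def test_beta_hydroxy_carbonyl_correction_detected(self, registry):
        counts = decompose(registry["4ohkic"])
        assert counts.get("hydroxy_carbonyl_1_3") == 1
        assert decompose(registry["hmbald"]).get(
            "hydroxy_carbonyl_1_3") == 1
        assert "hydroxy_carbonyl_1_3" not in decompose(registry["4ohleu"])


class TestReactionDrg:
    def test_alpha_kg_coupled_hydroxylation_is_highly_exergonic(
            self, registry, ipdo_pathway, group_table, conditions):
        """The first cascade reaction runs at around -100 kcal/mol or
        below at the default 1 mM conditions."""
        hx = ipdo_pathway.reactions[0]
        drg_kcal = reaction_drg(hx, registry.compounds, group_table,
                                conditions) / KJ_PER_KCAL
        assert drg_kcal <= -100.0

    def test_reverse_reaction_negates(self, registry, ipdo_pathway,
                                      group_table, conditions):
        rx = ipdo_pathway.reactions[1]
        fwd = reaction_drg(rx, registry.compounds, group_table, conditions)
        rev = reaction_drg(rx.reverse(), registry.compounds, group_table,
                           conditions)
        assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_empty_reaction_is_zero(self, registry, group_table, conditions):
        assert reaction_drg(Reaction("null", {}), registry.compounds,
                            group_table, conditions) == 0.0

    def test_concentration_term_uses_conditions(self, registry, ipdo_pathway,
                                                group_table):
        deam = ipdo_pathway.reactions[1]   # net +1/2 mol of solutes
        at_1mM = reaction_drg(deam, registry.compounds, group_table,
                              ThermoConditions(default_concentration=1e-3))
        at_1M = reaction_drg(deam, registry.compounds, group_table,
                             ThermoConditions(default_concentration=1.0))
        rt = ThermoConditions().rt
        assert at_1mM - at_1M == pytest.approx(0.5 * rt * math.log(1e-3))


class TestProfiles:
    def test_r1_steps_all_negative_with_decreasing_driving_force(
            self, registry, ipdo_orderings, group_table, conditions):
        prof = cascade_profile(ipdo_orderings["R1"], registry.compounds,
                               group_table, conditions, split_dr=True)
        values = prof.step_values_kj
        assert len(values) == 4
        assert all(v < 0 for v in values)
        assert values == sorted(values)   # hydroxylation the most negative

    def test_r1_more_harmonised_and_stronger_start_than_r3(
            self, registry, ipdo_orderings, group_table, conditions):
        p1 = cascade_profile(ipdo_orderings["R1"], registry.compounds,
                             group_table, conditions)
        p3 = cascade_profile(ipdo_orderings["R3"], registry.compounds,
                             group_table, conditions)
        assert p1.harmony_kj < p3.harmony_kj
        assert p1.step_values_kj[0] < p3.step_values_kj[0]

    def test_hess_additivity_endpoint_equals_overall_reaction(
            self, registry, ipdo_pathway, ipdo_orderings, group_table,
            conditions):
        overall = ipdo_pathway.overall_reaction()
        target = reaction_drg(overall, registry.compounds, group_table,
                              conditions)
        for label in ("R1", "R3"):
            for split in (False, True):
                prof = cascade_profile(ipdo_orderings[label],
                                       registry.compounds, group_table,
                                       conditions, split_dr=split)
                assert prof.endpoint_kj == pytest.approx(target, abs=1e-6)

    def test_equal_steps_have_zero_harmony(self):
        prof = ThermoProfile("X", [ProfileStep("a", [], -25.0),
                                   ProfileStep("b", [], -25.0),
                                   ProfileStep("c", [], -25.0)], "test")
        assert prof.harmony_kj == 0.0
        assert prof.bottleneck_kj == -25.0

    def test_impossible_route_has_no_profile(self, registry, ipdo_orderings,
                                             group_table, conditions):
        with pytest.raises(Exception, match="impossible"):
            cascade_profile(ipdo_orderings["R5"], registry.compounds,
                            group_table, conditions)


class TestCompareRoutes:
    def test_r1_ranked_first_with_identical_endpoints(
            self, registry, ipdo_orderings, group_table, conditions):
        profiles = [cascade_profile(ipdo_orderings[l], registry.compounds,
                                    group_table, conditions)
                    for l in ("R1", "R3")]
        ranking = compare_routes(profiles)
        assert ranking.order[0] == "R1"
        assert ranking.endpoint_kj == pytest.approx(
            profiles[0].endpoint_kj)

    def test_single_profile_trivially_ranked(self, registry, ipdo_orderings,
                                             group_table, conditions):
        p = cascade_profile(ipdo_orderings["R1"], registry.compounds,
                            group_table, conditions)
        assert compare_routes([p]).order == ["R1"]

    def test_corrupted_step_raises_consistency_error(
            self, registry, ipdo_orderings, group_table, conditions):
        p1 = cascade_profile(ipdo_orderings["R1"], registry.compounds,
                             group_table, conditions)
        p3 = cascade_profile(ipdo_orderings["R3"], registry.compounds,
                             group_table, conditions)
        p3.steps[1] = ProfileStep(p3.steps[1].label,
                                  p3.steps[1].reaction_ids,
                                  p3.steps[1].drg_kj + 5.0)
        with pytest.raises(ConsistencyError):
            compare_routes([p1, p3])


class TestPerturbation:
    def test_sigma_zero_is_identity(self, group_table):
        same = perturb_thermo_table(group_table, 0.0, seed=7)
        assert same.groups == group_table.groups
        assert same.version == group_table.version

    def test_seeded_noise_reproducible(self, group_table):
        a = perturb_thermo_table(group_table, 2.0, seed=11)
        b = perturb_thermo_table(group_table, 2.0, seed=11)
        assert a.groups == b.groups
        assert a.groups != group_table.groups

    def test_hydroxylation_sign_stable_under_noise(
            self, registry, ipdo_pathway, group_table, conditions):
        """sigma = 2 kJ/mol noise on the group contributions never flips
        the sign of the hydroxylation drG' (100 seeds): the step is two
        orders of magnitude more exergonic than the noise scale."""
        hx = ipdo_pathway.reactions[0]
        for seed in range(100):
            noisy = perturb_thermo_table(group_table, 2.0, seed=seed)
            assert reaction_drg(hx, registry.compounds, noisy,
                                conditions) < 0

    def test_perturbed_table_still_hess_additive(
            self, registry, ipdo_pathway, ipdo_orderings, conditions,
            group_table):
        noisy = perturb_thermo_table(group_table, 2.0, seed=3)
        prof = cascade_profile(ipdo_orderings["R1"], registry.compounds,
                               noisy, conditions)
        target = reaction_drg(ipdo_pathway.overall_reaction(),
                              registry.compounds, noisy, conditions)
        assert prof.endpoint_kj == pytest.approx(target, abs=1e-6)
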