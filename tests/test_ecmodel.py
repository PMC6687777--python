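"""Enzyme-constrained model construction and analysis.

The flux–enzyme coupling is checked against its closed form
(v_max = kcat · [E]), flux control coefficients against an independent
central-finite-difference oracle built from scratch per perturbation, and
the feasible-set containment of the constrained model against the base
model's optimum.
"""

import numpy as np
import pytest

from pangem import (
    EnzymeEntry,
    KcatEntry,
    Medium,
    Metabolite,
    Model,
    ModelError,
    PoolParams,
    Reaction,
    apply_medium,
    build_ec_model,
    ec_fva_compare,
    fba,
    flux_control_coefficients,
    simulate_parsimonious,
)
from pangem import fixtures as fx
from pangem.ecmodel import POOL_EXCHANGE


def one_step_model(gpr="gE"):
    mets = [Metabolite("s_e", compartment="e"), Metabolite("p_e", compartment="e")]
    rxns = [
        Reaction("EX_s", {"s_e": -1.0}, lower_bound=-1000.0),
        Reaction("CAT", {"s_e": -1.0, "p_e": 1.0}, gpr=gpr),
        Reaction("EX_p", {"p_e": -1.0}),
    ]
    return Model("one_step", mets, rxns, objective="EX_p")


class TestBuild:
    def test_max_flux_equals_kcat_times_concentration(self):
        # Eq-style closed form: v ≤ kcat·[E] = 1000 · 0.01 = 10, confirmed by LP.
        model = one_step_model()
        ec = build_ec_model(
            model,
            [KcatEntry("CAT", "gE", 1000.0)],
            [EnzymeEntry("gE", 30.0, concentration=0.01)],
        )
        assert fba(ec.model).objective_value == pytest.approx(10.0, rel=1e-9)

    def test_zero_concentration_blocks_the_reaction(self):
        ec = build_ec_model(
            one_step_model(),
            [KcatEntry("CAT", "gE", 1000.0)],
            [EnzymeEntry("gE", 30.0, concentration=0.0)],
        )
        assert fba(ec.model).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_isoenzymes_become_parallel_copies(self):
        ec = build_ec_model(
            one_step_model("gA or gB"),
            [KcatEntry("CAT", "gA", 100.0), KcatEntry("CAT", "gB", 100.0)],
            [EnzymeEntry("gA", 30.0), EnzymeEntry("gB", 30.0)],
        )
        copies = dict(ec.copies_of("CAT"))
        assert set(copies) == {"CAT_No1", "CAT_No2"}
        # each copy draws exactly one enzyme
        for cid in copies:
            enz = [m for m in ec.model.get_reaction(cid).stoichiometry
                   if m.startswith("prot_")]
            assert len(enz) == 1

    def test_complex_draws_all_subunits_in_one_reaction(self):
        ec = build_ec_model(
            one_step_model("gA and gB"),
            [KcatEntry("CAT", "gA", 100.0), KcatEntry("CAT", "gB", 200.0)],
            [EnzymeEntry("gA", 30.0), EnzymeEntry("gB", 30.0)],
        )
        stoich = ec.model.get_reaction("CAT").stoichiometry
        assert stoich["prot_gA"] == pytest.approx(-1 / 100.0)
        assert stoich["prot_gB"] == pytest.approx(-1 / 200.0)

    def test_reversible_catalyzed_reactions_split(self):
        model = one_step_model()
        model.get_reaction("CAT").lower_bound = -50.0
        ec = build_ec_model(
            model,
            [KcatEntry("CAT", "gE", 1000.0)],
            [EnzymeEntry("gE", 30.0)],
        )
        ids = set(ec.model.reaction_ids)
        assert "CAT" in ids and "CAT_REV" in ids
        assert ec.model.get_reaction("CAT_REV").lower_bound == 0.0
        assert ec.model.get_reaction("CAT_REV").upper_bound == 50.0

    def test_highest_kcat_wins_for_duplicates(self):
        ec = build_ec_model(
            one_step_model(),
            [KcatEntry("CAT", "gE", 100.0), KcatEntry("CAT", "gE", 1000.0)],
            [EnzymeEntry("gE", 30.0, concentration=0.01)],
        )
        assert fba(ec.model).objective_value == pytest.approx(10.0, rel=1e-9)

    def test_kcat_for_foreign_gene_rejected(self):
        with pytest.raises(ModelError, match="gX"):
            build_ec_model(
                one_step_model(),
                [KcatEntry("CAT", "gX", 10.0)],
                [EnzymeEntry("gX", 30.0)],
            )

    def test_nonpositive_kcat_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            KcatEntry("CAT", "gE", 0.0)

    def test_pool_relaxation_recovers_base_optimum(self, toy_model, toy_medium):
        kcats = fx.make_kcat_table(toy_model, seed=3)
        enzymes = fx.make_enzyme_table(toy_model, seed=3)
        ec = build_ec_model(toy_model, kcats, enzymes,
                            PoolParams(p_total=1e9, f=1.0, sigma=1.0))
        base = fba(apply_medium(toy_model, toy_medium)).objective_value
        relaxed = fba(apply_medium(ec.model, toy_medium)).objective_value
        assert relaxed == pytest.approx(base, rel=1e-9)

    def test_ec_optimum_never_exceeds_base(self, toy_model, toy_ec, toy_medium):
        base = fba(apply_medium(toy_model, toy_medium)).objective_value
        constrained = fba(apply_medium(toy_ec.model, toy_medium)).objective_value
        assert constrained <= base + 1e-9


class TestParsimonious:
    def test_single_route_matches_plain_fba(self, toy_ec, toy_medium):
        sol = simulate_parsimonious(toy_ec, toy_medium)
        plain = fba(apply_medium(toy_ec.model, toy_medium)).objective_value
        assert sol.objective_value == pytest.approx(plain, rel=1e-9)

    def test_prefers_the_faster_isoenzyme(self):
        ec = build_ec_model(
            one_step_model("gSlow or gFast"),
            [KcatEntry("CAT", "gSlow", 100.0), KcatEntry("CAT", "gFast", 1000.0)],
            [EnzymeEntry("gSlow", 30.0), EnzymeEntry("gFast", 30.0)],
        )
        ec.model.get_reaction("EX_s").lower_bound = -10.0
        sol = simulate_parsimonious(ec, Medium({"EX_s": 10.0}))
        usage = ec.enzyme_usage(sol.fluxes)
        assert usage["gSlow"] == pytest.approx(0.0, abs=1e-9)
        assert usage["gFast"] > 0

    def test_zero_growth_means_zero_usage(self, toy_ec):
        sol = simulate_parsimonious(toy_ec, Medium({"EX_glc": 0.0}))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert sol.protein_mass == pytest.approx(0.0, abs=1e-9)

    def test_growth_is_not_degraded_by_stage_two(self, toy_ec, toy_medium):
        sol = simulate_parsimonious(toy_ec, toy_medium)
        stage_one = fba(apply_medium(toy_ec.model, toy_medium)).objective_value
        assert abs(sol.objective_value - stage_one) <= 1e-9 * max(1.0, stage_one)


def central_difference_fcc(model, kcats, enzymes, pool, gene, medium, delta=0.001):
    """Independent oracle: rebuild the ec model at kcat·(1±δ) and take the
    central difference of the re-optimized objective."""
    def growth(factor):
        scaled = [
            KcatEntry(k.reaction_id, k.gene_id,
                      k.kcat * factor if k.gene_id == gene else k.kcat)
            for k in kcats
        ]
        ec = build_ec_model(model, scaled, enzymes, pool)
        return fba(apply_medium(ec.model, medium)).objective_value

    v_b = growth(1.0)
    return ((growth(1 + delta) - growth(1 - delta)) / (2 * delta)) / v_b


class TestFCC:
    def test_fully_limiting_enzyme_has_unit_control(self):
        ec = build_ec_model(
            one_step_model(),
            [KcatEntry("CAT", "gE", 1000.0)],
            [EnzymeEntry("gE", 30.0, concentration=0.01)],
        )
        res = flux_control_coefficients(ec)
        assert res.coefficients["gE"] == pytest.approx(1.0, abs=1e-3)

    def test_non_binding_enzyme_has_zero_control(self):
        model = one_step_model()
        model.get_reaction("EX_s").lower_bound = -1.0  # substrate-limited
        ec = build_ec_model(
            model,
            [KcatEntry("CAT", "gE", 1000.0)],
            [EnzymeEntry("gE", 30.0, concentration=1.0)],
        )
        res = flux_control_coefficients(ec)
        assert res.coefficients["gE"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_base_flux_is_flagged_not_zeroed(self, toy_ec):
        res = flux_control_coefficients(toy_ec, medium=Medium({"EX_glc": 0.0}))
        assert res.undefined
        assert res.coefficients == {}

    def test_sequential_limiting_steps_share_control(self):
        # Two mandatory sequential catalyzed steps under one pool: control
        # sums to ≈ 1 (brute-force perturbation on the same toy agrees).
        mets = [Metabolite("s_e", compartment="e"), Metabolite("m_c"),
                Metabolite("p_e", compartment="e")]
        rxns = [
            Reaction("EX_s", {"s_e": -1.0}, lower_bound=-1000.0),
            Reaction("CAT1", {"s_e": -1.0, "m_c": 1.0}, gpr="gA"),
            Reaction("CAT2", {"m_c": -1.0, "p_e": 1.0}, gpr="gB"),
            Reaction("EX_p", {"p_e": -1.0}),
        ]
        model = Model("two_step", mets, rxns, objective="EX_p")
        kcats = [KcatEntry("CAT1", "gA", 500.0), KcatEntry("CAT2", "gB", 2000.0)]
        enzymes = [EnzymeEntry("gA", 40.0), EnzymeEntry("gB", 25.0)]
        ec = build_ec_model(model, kcats, enzymes)
        res = flux_control_coefficients(ec)
        assert sum(res.coefficients.values()) == pytest.approx(1.0, abs=1e-3)

    def test_matches_central_difference_oracle(self, toy_model, toy_medium):
        # Concentration-bounded enzymes keep growth piecewise linear in each
        # kcat, where the one-sided and central differences coincide.
        kcats = fx.make_kcat_table(toy_model, seed=7)
        enzymes = fx.make_enzyme_table(toy_model, seed=7, concentration=0.004)
        pool = PoolParams()
        ec = build_ec_model(toy_model, kcats, enzymes, pool)
        res = flux_control_coefficients(ec, medium=toy_medium)
        for gene in ["gC1a", "gI1a", "g_aa"]:
            oracle = central_difference_fcc(
                toy_model, kcats, enzymes, pool, gene, toy_medium
            )
            assert res.coefficients[gene] == pytest.approx(oracle, abs=1e-4)


class TestECFVA:
    def test_enzyme_pool_shrinks_variability(self):
        spec = fx.ToySpec(n_parallel_routes=2)
        model = fx.make_toy_gem(spec)
        ec = build_ec_model(
            model, fx.make_kcat_table(model, seed=11), fx.make_enzyme_table(model, seed=11)
        )
        ranges = ec_fva_compare(model, ec, fx.minimal_medium(model))
        base_width = sum(hi - lo for (lo, hi), _ in ranges.values())
        ec_width = sum(hi - lo for _, (lo, hi) in ranges.values())
        assert ec_width <= base_width + 1e-6
        assert base_width > 1e-3  # the parallel routes really create slack

    def test_relaxed_constraints_reproduce_base_ranges(self, toy_model, toy_medium):
        ec = build_ec_model(
            toy_model,
            fx.make_kcat_table(toy_model, seed=5, kcat_range=(1e9, 1e9)),
            fx.make_enzyme_table(toy_model, seed=5),
            PoolParams(p_total=1e9, f=1.0, sigma=1.0),
        )
        ranges = ec_fva_compare(toy_model, ec, toy_medium)
        for rid, ((lo_b, hi_b), (lo_e, hi_e)) in ranges.items():
            if rid == POOL_EXCHANGE:
                continue
            assert lo_e == pytest.approx(lo_b, abs=1e-5)
            assert hi_e == pytest.approx(hi_b, abs=1e-5)

    def test_single_pathway_has_no_variability_anywhere(self, toy_model, toy_ec, toy_medium):
        ranges = ec_fva_compare(toy_model, toy_ec, toy_medium)
        for (lo_b, hi_b), (lo_e, hi_e) in ranges.values():
            assert hi_b - lo_b == pytest.approx(0.0, abs=1e-6)
            assert hi_e - lo_e == pytest.approx(0.0, abs=1e-6)

    def test_projection_sums_copies(self, toy_ec, toy_medium):
        sol = simulate_parsimonious(toy_ec, toy_medium)
        parent = toy_ec.project(sol.fluxes)
        copies = toy_ec.copies_of("R_iso1")
        assert len(copies) == 2
        assert parent["R_iso1"] == pytest.approx(
            sum(sign * sol.fluxes[cid] for cid, sign in copies)
        )
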