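"""Validation statistics, substrate screens, essentiality, chemostats, yields."""

import itertools
import math

import numpy as np
import pytest

from pangem import (
    ConfusionMatrix,
    Medium,
    Metabolite,
    Model,
    ModelError,
    Reaction,
    SubstrateEntry,
    apply_medium,
    chemostat_sim,
    fba,
    gene_essentiality,
    growth_prediction_error,
    max_product_yield,
    score_predictions,
    substrate_screen,
)
from pangem import fixtures as fx
from pangem.io import to_cobra


def contingency_oracle(tp, tn, fp, fn):
    """Textbook 2×2 association measures computed from first principles."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    margins = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if margins == 0 else (tp * tn - fp * fn) / math.sqrt(margins)
    return acc, mcc


class TestScores:
    def test_perfect_agreement(self):
        pred = {"a": True, "b": False, "c": True}
        cm, acc, mcc = score_predictions(pred, dict(pred))
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 1, 0, 0)
        assert acc == 1.0 and mcc == pytest.approx(1.0)

    def test_balanced_noise_scores_half_and_zero(self):
        cm = ConfusionMatrix(1, 1, 1, 1)
        assert cm.accuracy == pytest.approx(0.5)
        assert cm.mcc()[0] == pytest.approx(0.0)

    def test_hand_worked_example(self):
        cm = ConfusionMatrix(2, 2, 1, 1)
        assert cm.accuracy == pytest.approx(4 / 6)
        assert cm.mcc()[0] == pytest.approx(1 / 3)

    def test_zero_marginal_reports_undefined_with_name(self):
        mcc, reason = ConfusionMatrix(0, 5, 0, 3).mcc()
        assert mcc is None and "TP+FP" in reason

    def test_exhaustive_contingency_oracle_agreement(self):
        for tp, tn, fp, fn in itertools.product(range(5), repeat=4):
            if tp + tn + fp + fn == 0:
                continue
            cm = ConfusionMatrix(tp, tn, fp, fn)
            acc, mcc = contingency_oracle(tp, tn, fp, fn)
            assert cm.accuracy == pytest.approx(acc)
            got = cm.mcc()[0]
            if mcc is None:
                assert got is None
            else:
                assert got == pytest.approx(mcc)

    def test_independent_predictions_have_small_mcc(self):
        rng = np.random.default_rng(42)
        items = [f"i{k}" for k in range(400)]
        pred = {i: bool(rng.integers(2)) for i in items}
        obs = {i: bool(rng.integers(2)) for i in items}
        _, _, mcc = score_predictions(pred, obs)
        assert abs(mcc) < 0.2

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            score_predictions({"a": True}, {"b": True})


class TestSubstrateScreen:
    def panel(self):
        return [
            SubstrateEntry("glucose", "EX_glc", "carbon"),
            SubstrateEntry("fructose", "EX_fru", "carbon"),
            SubstrateEntry("xylose", "EX_xyl", "carbon"),
        ]

    def test_usable_and_unusable_substrates(self, toy_model):
        toy_model.add_metabolite(Metabolite("xyl_e", compartment="e"))
        toy_model.add_reaction(
            Reaction("EX_xyl", {"xyl_e": -1.0}, lower_bound=0.0)
        )  # no consuming pathway: a dead-end uptake
        calls = substrate_screen(toy_model, self.panel(), Medium())
        assert calls["glucose"] == "growth"
        assert calls["fructose"] == "growth"
        assert calls["xylose"] == "no-growth"

    def test_missing_exchange_reported_separately(self, toy_model):
        calls = substrate_screen(toy_model, self.panel(), Medium())
        assert calls["xylose"] == "not-mappable"

    def test_order_independent(self, toy_model):
        forward = substrate_screen(toy_model, self.panel(), Medium())
        backward = substrate_screen(toy_model, self.panel()[::-1], Medium())
        assert forward == backward

    def test_model_not_mutated(self, toy_model):
        before = {r.id: (r.lower_bound, r.upper_bound) for r in toy_model.reactions}
        substrate_screen(toy_model, self.panel(), Medium())
        after = {r.id: (r.lower_bound, r.upper_bound) for r in toy_model.reactions}
        assert before == after


class TestEssentiality:
    def test_sole_pathway_gene_is_essential(self, toy_model, toy_medium):
        essential = gene_essentiality(toy_model, toy_medium)
        assert "g_aa" in essential
        assert "gC1a" in essential and "gC1b" in essential

    def test_isoenzymes_are_dispensable(self, toy_model, toy_medium):
        essential = gene_essentiality(toy_model, toy_medium)
        assert "gI1a" not in essential and "gI1b" not in essential

    def test_matches_cobrapy_deletion_oracle(self, toy_model, toy_medium):
        from cobra.flux_analysis import single_gene_deletion

        essential = gene_essentiality(toy_model, toy_medium)
        cmodel = to_cobra(apply_medium(toy_model, toy_medium))
        wt = cmodel.slim_optimize()
        deletions = single_gene_deletion(cmodel, processes=1)
        oracle = set()
        for _, row in deletions.iterrows():
            growth = 0.0 if np.isnan(row["growth"]) else row["growth"]
            if growth < 0.05 * wt:
                oracle |= set(row["ids"])
        assert essential == oracle

    def test_richer_medium_never_creates_essentiality(self, toy_model):
        poor = gene_essentiality(toy_model, Medium({"EX_glc": 10.0}))
        rich = gene_essentiality(toy_model, Medium({"EX_glc": 10.0, "EX_fru": 10.0}))
        assert rich <= poor


class TestChemostat:
    def biomass_model(self):
        mets = [
            Metabolite("s_e", compartment="e"),
            Metabolite("prot_c"),
            Metabolite("carb_c"),
        ]
        rxns = [
            Reaction("EX_s", {"s_e": -1.0}, lower_bound=-1000.0),
            Reaction("MK_PROT", {"s_e": -2.0, "prot_c": 1.0}),
            Reaction("MK_CARB", {"s_e": -1.0, "carb_c": 1.0}),
            Reaction("BIO", {"prot_c": -1.0, "carb_c": -1.0}),
        ]
        return Model("chem", mets, rxns, objective="BIO")

    def test_glucose_limited_growth_equals_fba_at_bound(self, toy_model):
        sol = chemostat_sim(toy_model, {"EX_glc": 10.0})
        ref = fba(apply_medium(toy_model, Medium({"EX_glc": 10.0})))
        assert sol.objective_value == pytest.approx(ref.objective_value)

    def test_rescale_one_is_identity(self):
        plain = chemostat_sim(self.biomass_model(), {"EX_s": 9.0})
        scaled = chemostat_sim(
            self.biomass_model(), {"EX_s": 9.0}, limitation="nitrogen",
            protein_rescale=1.0, protein_metabolite="prot_c",
        )
        assert scaled.objective_value == pytest.approx(plain.objective_value)

    def test_rescaled_biomass_matches_hand_stoichiometry(self):
        # protein 1.0 → 0.5, freed 0.5 redistributed onto carb: 1.0 → 1.5.
        # Substrate per biomass: 0.5·2 + 1.5·1 = 2.5 → growth = 9/2.5 = 3.6.
        sol = chemostat_sim(
            self.biomass_model(), {"EX_s": 9.0}, limitation="nitrogen",
            protein_rescale=0.5, protein_metabolite="prot_c",
        )
        assert sol.objective_value == pytest.approx(9.0 / 2.5)

    def test_bad_rescale_rejected(self):
        with pytest.raises(ModelError):
            chemostat_sim(self.biomass_model(), {"EX_s": 9.0},
                          limitation="nitrogen", protein_rescale=1.5,
                          protein_metabolite="prot_c")


class TestYields:
    def test_one_to_one_pathway_has_unit_mol_yield(self):
        mets = [Metabolite("s_e", compartment="e", formula="C6H12O6"),
                Metabolite("p_e", compartment="e", formula="C6H12O6")]
        rxns = [
            Reaction("EX_s", {"s_e": -1.0}, lower_bound=-10.0),
            Reaction("CONV", {"s_e": -1.0, "p_e": 1.0}),
            Reaction("EX_p", {"p_e": -1.0}),
        ]
        model = Model("y", mets, rxns, objective="EX_p")
        res = max_product_yield(model, "EX_p", "EX_s")
        assert res.value == pytest.approx(1.0)

    def test_carbon_loss_shows_in_cmol_yield(self):
        # 3-carbon substrate loses one carbon as CO2: Cmol yield 2/3.
        mets = [
            Metabolite("s_e", compartment="e", formula="C3H6O3"),
            Metabolite("p_e", compartment="e", formula="C2H4O2"),
            Metabolite("co2_e", compartment="e", formula="CO2"),
        ]
        rxns = [
            Reaction("EX_s", {"s_e": -1.0}, lower_bound=-10.0),
            Reaction("SPLIT", {"s_e": -1.0, "p_e": 1.0, "co2_e": 1.0}),
            Reaction("EX_p", {"p_e": -1.0}),
            Reaction("EX_co2", {"co2_e": -1.0}),
        ]
        model = Model("y", mets, rxns, objective="EX_p")
        assert max_product_yield(model, "EX_p", "EX_s").value == pytest.approx(1.0)
        cmol = max_product_yield(model, "EX_p", "EX_s", basis="cmol")
        assert cmol.value == pytest.approx(2 / 3)

    def test_blocked_product_yields_zero_with_flag(self, toy_model):
        res = max_product_yield(toy_model, "EX_fru", "EX_glc")
        assert res.value == 0.0 and res.blocked


class TestGrowthError:
    def test_exact_predictions_have_zero_error(self):
        pred = {"c1": 0.4, "c2": 0.2, "ref": 0.3}
        assert growth_prediction_error(pred, dict(pred), "ref") == pytest.approx(0.0)

    def test_uniform_double_is_hundred_percent(self):
        meas = {"c1": 0.2, "c2": 0.1, "ref": 0.3}
        pred = {"c1": 0.4, "c2": 0.2, "ref": 0.3}
        # reference matches, others are exactly 2× the scaled measurement
        assert growth_prediction_error(pred, meas, "ref") == pytest.approx(
            100.0 * (1.0 + 1.0 + 0.0) / 3
        )

    def test_three_condition_hand_arithmetic(self):
        meas = {"ref": 0.5, "a": 0.25, "b": 0.1}
        pred = {"ref": 0.4, "a": 0.3, "b": 0.06}
        # scale = 0.4/0.5 = 0.8 → scaled a = 0.2, b = 0.08
        expected = 100.0 * (abs(0.3 - 0.2) / 0.2 + abs(0.06 - 0.08) / 0.08 + 0.0) / 3
        assert growth_prediction_error(pred, meas, "ref") == pytest.approx(expected)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            growth_prediction_error({"a": 1.0}, {"a": 1.0}, "ref")
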