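"""In-silico phenotype screens and validation statistics.

Covers the standard ways a genome-scale model is confronted with
experimental data: Biolog-style substrate usage screens, gene essentiality
against deletion collections, chemostat simulations at fixed uptake rates,
maximum product yields, and growth-rate prediction error — scored with
accuracy and Matthews' correlation coefficient over the growth/no-growth
confusion matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .fba import Infeasible, Unbounded, fba
from .gpr import evaluate_gpr
from .model import Medium, Model, ModelError, apply_medium

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "SubstrateEntry",
    "score_predictions",
    "substrate_screen",
    "gene_essentiality",
    "chemostat_sim",
    "max_product_yield",
    "growth_prediction_error",
]

DEFAULT_UPTAKE = 10.0  # mmol·gDW⁻¹·h⁻¹, the conventional in-silico uptake rate
GROWTH_CALL_THRESHOLD = 1e-4  # h⁻¹; objective above this counts as growth


@dataclass(frozen=True)
class ConfusionMatrix:
    """Growth/no-growth agreement counts.

    TP: in vivo growth / in silico growth, TN: no growth in both,
    FP: in vivo no growth / in silico growth, FN: in vivo growth / in silico
    no growth.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return (self.tp + self.tn) / self.total

    def mcc(self) -> Tuple[Optional[float], Optional[str]]:
        """Matthews' correlation coefficient, or ``(None, reason)`` when a
        marginal total is zero and the coefficient is undefined."""
        factors = {
            "TP+FP": self.tp + self.fp,
            "TP+FN": self.tp + self.fn,
            "TN+FP": self.tn + self.fp,
            "TN+FN": self.tn + self.fn,
        }
        for name, value in factors.items():
            if value == 0:
                return None, f"undefined: marginal {name} is zero"
        num = self.tp * self.tn - self.fp * self.fn
        den = math.sqrt(math.prod(factors.values()))
        return num / den, None


def score_predictions(
    predicted: Mapping[str, bool], observed: Mapping[str, bool]
) -> Tuple[ConfusionMatrix, float, Optional[float]]:
    """Confusion matrix, accuracy and MCC of binary growth calls.

    ``predicted`` and ``observed`` must cover the same items.  Accuracy is
    (TP+TN)/(TP+TN+FP+FN); MCC is the usual normalized determinant of the
    2×2 table, ``None`` (with the zero marginal logged) when undefined.
    """
    if set(predicted) != set(observed):
        raise ValueError("predicted and observed cover different items")
    tp = tn = fp = fn = 0
    for item, pred in predicted.items():
        obs = observed[item]
        if obs and pred:
            tp += 1
        elif not obs and not pred:
            tn += 1
        elif not obs and pred:
            fp += 1
        else:
            fn += 1
    cm = ConfusionMatrix(tp, tn, fp, fn)
    mcc, reason = cm.mcc()
    if reason:
        logger.warning("MCC %s", reason)
    return cm, cm.accuracy, mcc


@dataclass(frozen=True)
class SubstrateEntry:
    """One substrate of a usage screen panel."""

    name: str
    exchange_id: str
    element_class: str  # carbon | nitrogen | phosphorus | sulphur


def substrate_screen(
    model: Model,
    panel: Iterable[SubstrateEntry],
    base_medium: Medium,
    growth_threshold: float = GROWTH_CALL_THRESHOLD,
    uptake: float = DEFAULT_UPTAKE,
) -> Dict[str, str]:
    """Growth/no-growth call per substrate, Biolog style.

    ``base_medium`` must omit the element class being varied; each substrate's
    exchange is opened at ``uptake`` on top of it, growth is maximized, and
    the call is ``"growth"`` iff the objective exceeds ``growth_threshold``.
    Substrates whose exchange is missing from the model are reported as
    ``"not-mappable"``.  The model is never mutated.
    """
    calls: Dict[str, str] = {}
    for entry in panel:
        if not model.has_reaction(entry.exchange_id):
            calls[entry.name] = "not-mappable"
            continue
        medium = Medium(base_medium)
        medium[entry.exchange_id] = uptake
        try:
            growth = fba(apply_medium(model, medium)).objective_value
        except (Infeasible, Unbounded):
            growth = 0.0
        calls[entry.name] = "growth" if growth > growth_threshold else "no-growth"
    return calls


def knockout_model(model: Model, genes: Iterable[str]) -> Model:
    """Copy of ``model`` with reactions disabled whose GPR fails without
    ``genes`` (flux bounds forced to zero; structure untouched)."""
    removed = set(genes)
    remaining = model.genes - removed
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.gpr.is_empty and not evaluate_gpr(rxn.gpr, remaining):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def gene_essentiality(
    model: Model,
    medium: Medium,
    threshold_fraction: float = 0.05,
) -> set:
    """Single-gene deletion screen: genes whose loss drops growth below
    ``threshold_fraction`` × wild type."""
    wt_model = apply_medium(model, medium)
    wild_type = fba(wt_model).objective_value
    if wild_type <= 0:
        raise ModelError("wild type does not grow on the given medium")
    essential = set()
    for gene in sorted(model.genes):
        mutant = knockout_model(wt_model, [gene])
        try:
            growth = fba(mutant).objective_value
        except Infeasible:
            growth = 0.0
        if growth < threshold_fraction * wild_type:
            essential.add(gene)
    return essential


def chemostat_sim(
    model: Model,
    uptake_bounds: Mapping[str, float],
    limitation: str = "glucose",
    protein_rescale: Optional[float] = None,
    protein_metabolite: Optional[str] = None,
    close_other_uptakes: bool = True,
) -> "FluxDistribution":
    """Chemostat simulation at measured uptake rates.

    Lower bounds of the named exchange reactions are fixed to the negative of
    the given magnitudes (maximum uptake), then growth is maximized.  A
    chemostat runs on a defined medium, so uptake through every other
    exchange is closed unless ``close_other_uptakes`` is disabled.  Under
    nitrogen limitation the protein content of biomass drops, so the biomass
    coefficient of ``protein_metabolite`` is multiplied by
    ``protein_rescale`` ∈ (0, 1] and the freed coefficient mass is
    redistributed proportionally over the other consumed biomass components.
    """
    out = model.copy()
    for rid, rate in uptake_bounds.items():
        rxn = out.get_reaction(rid)
        if not rxn.is_exchange:
            raise ModelError(f"uptake bound target {rid!r} is not an exchange")
        rxn.lower_bound = -abs(rate)
    if close_other_uptakes:
        for rxn in out.reactions:
            if rxn.is_exchange and rxn.id not in uptake_bounds:
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
    if protein_rescale is not None:
        if not 0.0 < protein_rescale <= 1.0:
            raise ModelError(f"protein_rescale must be in (0, 1], got {protein_rescale}")
        if limitation != "nitrogen":
            raise ModelError("protein rescaling applies to nitrogen limitation only")
        if protein_metabolite is None:
            raise ModelError("nitrogen limitation needs the biomass protein metabolite id")
        biomass = out.get_reaction(out.objective)
        coef = biomass.stoichiometry.get(protein_metabolite)
        if coef is None or coef >= 0:
            raise ModelError(
                f"{protein_metabolite!r} is not a consumed component of the biomass reaction"
            )
        freed = -coef * (1.0 - protein_rescale)
        biomass.stoichiometry[protein_metabolite] = coef * protein_rescale
        others = [
            mid
            for mid, c in biomass.stoichiometry.items()
            if c < 0 and mid != protein_metabolite
        ]
        other_total = -sum(biomass.stoichiometry[mid] for mid in others)
        if others and other_total > 0:
            scale = (other_total + freed) / other_total
            for mid in others:
                biomass.stoichiometry[mid] *= scale
    return fba(out)


@dataclass
class YieldResult:
    value: float
    basis: str
    blocked: bool = False


def max_product_yield(
    model: Model,
    product_exchange: str,
    substrate_exchange: str,
    basis: str = "mol",
    uptake: float = DEFAULT_UPTAKE,
    growth: float = 0.0,
) -> YieldResult:
    """Maximum product yield on a substrate at fixed (default zero) growth.

    Yield = v_product / |v_substrate| per mol, or weighted by carbon counts
    from the metabolite formulas for the Cmol basis.  A product that cannot
    be exported yields 0 with the ``blocked`` flag set.
    """
    if basis not in ("mol", "cmol"):
        raise ValueError("basis must be 'mol' or 'cmol'")
    out = model.copy()
    sub = out.get_reaction(substrate_exchange)
    sub.lower_bound = -abs(uptake)
    if out.objective is not None and out.objective != product_exchange:
        obj = out.get_reaction(out.objective)
        obj.lower_bound = growth
        obj.upper_bound = growth
    sol = fba(out, product_exchange)
    v_prod = sol.objective_value
    v_sub = abs(sol.fluxes[substrate_exchange])
    if v_prod <= 0 or v_sub == 0:
        return YieldResult(0.0, basis, blocked=True)
    y = v_prod / v_sub
    if basis == "cmol":
        def carbon(exchange_id: str) -> float:
            rxn = model.get_reaction(exchange_id)
            (met_id,) = rxn.stoichiometry
            formula = model.get_metabolite(met_id).formula or {}
            return formula.get("C", 0.0)

        c_prod, c_sub = carbon(product_exchange), carbon(substrate_exchange)
        if c_sub == 0:
            raise ModelError(f"substrate of {substrate_exchange!r} has no carbon")
        y *= c_prod / c_sub
    return YieldResult(y, basis)


def growth_prediction_error(
    predicted: Mapping[str, float],
    measured: Mapping[str, float],
    reference_condition: str,
) -> float:
    """Mean relative growth-rate error (%) after reference scaling.

    Measured rates are rescaled so the reference condition matches its
    prediction (relative phenotyping data carries no absolute scale); the
    error is the mean of |pred − scaled| / scaled over conditions, as a
    percentage.  Conditions with a zero scaled measurement are excluded and
    logged.
    """
    if reference_condition not in measured:
        raise ValueError(f"reference condition {reference_condition!r} not measured")
    if set(predicted) != set(measured):
        raise ValueError("predicted and measured cover different conditions")
    if measured[reference_condition] == 0:
        raise ValueError("reference measurement is zero; cannot scale")
    scale = predicted[reference_condition] / measured[reference_condition]
    errors: List[float] = []
    for cond, meas in measured.items():
        scaled = meas * scale
        if scaled == 0:
            logger.warning("condition %r excluded: zero scaled measurement", cond)
            continue
        errors.append(abs(predicted[cond] - scaled) / scaled)
    if not errors:
        raise ValueError("no usable conditions")
    return 100.0 * sum(errors) / len(errors)
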