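"""Enzyme-constrained model construction and analysis.

Extends a stoichiometric model with enzyme capacity constraints in the
GECKO style.  Each catalyzed reaction j draws its enzyme i as a
pseudo-metabolite with stoichiometric coefficient −1/kcat_ij, so that at
steady state the enzyme usage e_i satisfies

    e_i = Σ_j v_j / kcat_ij            (flux–enzyme coupling)
    0 ≤ e_i ≤ [E_i]                    (measured concentration bound)
    v_j ≤ kcat_ij · [E_i]              (implied capacity bound)

Enzymes without a measured concentration draw from a shared protein pool
instead, limited to P_total · f · σ grams of enzyme per gram dry weight
(total protein content × metabolic-enzyme mass fraction × average
saturation).

Isoenzymes (OR in the GPR) become parallel copies of the reaction, each
coupled to one alternative; complexes (AND) draw every subunit within one
reaction.  Reversible catalyzed reactions are split into irreversible
forward/backward pairs so the coupling coefficient has a consistent sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .fba import Infeasible, fba, optimize
from .model import (
    DEFAULT_UPPER,
    FluxDistribution,
    Medium,
    Metabolite,
    Model,
    ModelError,
    Reaction,
    apply_medium,
)

__all__ = [
    "KcatEntry",
    "EnzymeEntry",
    "PoolParams",
    "ECModel",
    "ParsimoniousSolution",
    "FCCResult",
    "build_ec_model",
    "simulate_parsimonious",
    "flux_control_coefficients",
    "ec_fva_compare",
]

ENZYME_COMPARTMENT = "enzyme"
POOL_MET = "prot_pool"
POOL_EXCHANGE = "prot_pool_exchange"


@dataclass(frozen=True)
class KcatEntry:
    """Turnover number (h⁻¹) of one enzyme for one reaction."""

    reaction_id: str
    gene_id: str
    kcat: float

    def __post_init__(self):
        if not self.kcat > 0:
            raise ValueError(
                f"kcat must be positive, got {self.kcat} for "
                f"({self.reaction_id}, {self.gene_id})"
            )


@dataclass(frozen=True)
class EnzymeEntry:
    """Molecular weight (g·mmol⁻¹) and optional concentration bound
    [E_i] (mmol·gDW⁻¹) for one enzyme."""

    gene_id: str
    molecular_weight: float
    concentration: Optional[float] = None

    def __post_init__(self):
        if not self.molecular_weight > 0:
            raise ValueError(f"molecular weight must be positive ({self.gene_id})")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError(f"concentration bound must be ≥ 0 ({self.gene_id})")


@dataclass(frozen=True)
class PoolParams:
    """Shared protein-pool capacity: P_total · f · σ (g enzyme per gDW)."""

    p_total: float = 0.5  # total protein content, g protein · gDW⁻¹
    f: float = 0.5  # mass fraction of protein that is model enzymes
    sigma: float = 0.5  # average in vivo enzyme saturation

    @property
    def capacity(self) -> float:
        return self.p_total * self.f * self.sigma


@dataclass
class ECModel:
    """An enzyme-constrained model plus the bookkeeping to map back to its parent.

    ``parent_map`` sends every reaction id of the ec model to
    ``(parent_reaction_id, sign)``; summing ``sign · v`` over the preimage of
    a parent reaction recovers its net flux in the original namespace.
    Enzyme draw reactions and the pool exchange map to themselves.
    """

    model: Model
    parent_map: Dict[str, Tuple[str, float]]
    usage_reactions: Dict[str, str]  # gene id -> draw reaction id
    enzymes: Dict[str, EnzymeEntry]
    kcats: Dict[Tuple[str, str], float]  # (ec reaction id, gene id) -> kcat
    pool: PoolParams = field(default_factory=PoolParams)

    def project(self, fluxes: Mapping[str, float]) -> Dict[str, float]:
        """Project ec-model fluxes onto the parent reaction namespace."""
        out: Dict[str, float] = {}
        for rid, v in fluxes.items():
            parent, sign = self.parent_map.get(rid, (rid, 1.0))
            out[parent] = out.get(parent, 0.0) + sign * v
        return out

    def copies_of(self, parent_id: str) -> List[Tuple[str, float]]:
        return [
            (rid, sign)
            for rid, (pid, sign) in self.parent_map.items()
            if pid == parent_id
        ]

    def enzyme_usage(self, fluxes: Mapping[str, float]) -> Dict[str, float]:
        """Enzyme usage e_i (mmol·gDW⁻¹) from a flux vector."""
        return {g: fluxes.get(rid, 0.0) for g, rid in self.usage_reactions.items()}

    def protein_mass(self, fluxes: Mapping[str, float]) -> float:
        """Total enzyme mass Σ MW_i · e_i (g·gDW⁻¹)."""
        usage = self.enzyme_usage(fluxes)
        return sum(self.enzymes[g].molecular_weight * e for g, e in usage.items())

    def copy(self) -> "ECModel":
        return ECModel(
            self.model.copy(),
            dict(self.parent_map),
            dict(self.usage_reactions),
            dict(self.enzymes),
            dict(self.kcats),
            self.pool,
        )


def _dnf_branches(node) -> List[frozenset]:
    """Minimal AND gene-sets (isoenzyme alternatives) of a GPR tree."""
    if node is None:
        return []
    if isinstance(node, str):
        return [frozenset([node])]
    op, children = node
    child_branches = [_dnf_branches(c) for c in children]
    if op == "or":
        out: List[frozenset] = []
        for branches in child_branches:
            out.extend(branches)
        return out
    # AND: cartesian product of the children's alternatives
    out = [frozenset()]
    for branches in child_branches:
        out = [acc | b for acc in out for b in branches]
    return out


def build_ec_model(
    model: Model,
    kcats: Iterable[KcatEntry],
    enzymes: Iterable[EnzymeEntry],
    pool: PoolParams = PoolParams(),
) -> ECModel:
    """Attach enzyme constraints to ``model``.

    Every kcat entry must name an existing reaction and a gene occurring in
    that reaction's GPR.  When several kcats exist for one (reaction, gene)
    pair the largest is used.  Genes appearing in kcat entries must have an
    ``EnzymeEntry`` (the molecular weight is needed both for pool accounting
    and for parsimonious usage minimisation).
    """
    enzyme_by_gene = {e.gene_id: e for e in enzymes}

    # Collect the best kcat per (reaction, gene), validating as we go.
    best: Dict[Tuple[str, str], float] = {}
    for entry in kcats:
        rxn = model.get_reaction(entry.reaction_id)  # KeyError if unknown
        if entry.gene_id not in rxn.gpr.genes():
            raise ModelError(
                f"kcat for gene {entry.gene_id!r} rejected: not in the GPR of "
                f"reaction {entry.reaction_id!r}"
            )
        if entry.gene_id not in enzyme_by_gene:
            raise ModelError(
                f"no enzyme entry (molecular weight) for gene {entry.gene_id!r}"
            )
        key = (entry.reaction_id, entry.gene_id)
        best[key] = max(best.get(key, 0.0), entry.kcat)

    catalyzed = sorted({rid for rid, _ in best})
    ec = Model(
        f"ec_{model.id}",
        [m for m in model.metabolites],
        [],
        set(model.genes),
        model.objective,
    )
    parent_map: Dict[str, Tuple[str, float]] = {}
    ec_kcats: Dict[Tuple[str, str], float] = {}

    used_genes = sorted({g for _, g in best})
    for gene in used_genes:
        ec.add_metabolite(Metabolite(f"prot_{gene}", compartment=ENZYME_COMPARTMENT))

    def coupled_copy(rxn: Reaction, suffix: str, stoich, lb, ub, branch) -> None:
        new_id = rxn.id + suffix
        stoich = dict(stoich)
        for gene in sorted(branch):
            kappa = best.get((rxn.id, gene))
            if kappa is None:
                continue  # subunit without kinetic data carries no enzyme cost
            stoich[f"prot_{gene}"] = stoich.get(f"prot_{gene}", 0.0) - 1.0 / kappa
            ec_kcats[(new_id, gene)] = kappa
        new = Reaction(
            new_id,
            stoich,
            name=rxn.name,
            lower_bound=lb,
            upper_bound=ub,
            gpr=rxn.gpr if not branch else " and ".join(sorted(branch)),
            subsystem=rxn.subsystem,
        )
        sign = -1.0 if suffix.endswith("_REV") else 1.0
        parent_map[new_id] = (rxn.id, sign)
        ec.add_reaction(new)

    for rxn in model.reactions:
        if rxn.id not in catalyzed:
            ec.add_reaction(rxn.copy())
            parent_map[rxn.id] = (rxn.id, 1.0)
            continue
        branches = _dnf_branches(rxn.gpr.root)
        # Directions: split reversible catalyzed reactions.
        directions = []
        if rxn.upper_bound > 0:
            directions.append(("", rxn.stoichiometry, max(rxn.lower_bound, 0.0), rxn.upper_bound))
        if rxn.lower_bound < 0:
            back = {m: -c for m, c in rxn.stoichiometry.items()}
            directions.append(("_REV", back, 0.0, -rxn.lower_bound))
        multi = len(branches) > 1
        for dir_suffix, stoich, lb, ub in directions:
            if multi:
                for k, branch in enumerate(
                    sorted(branches, key=lambda b: sorted(b)), start=1
                ):
                    coupled_copy(rxn, f"_No{k}{dir_suffix}", stoich, lb, ub, branch)
            else:
                branch = branches[0] if branches else frozenset()
                coupled_copy(rxn, dir_suffix, stoich, lb, ub, branch)

    # Protein pool and per-enzyme draw reactions.
    pool_needed = any(
        enzyme_by_gene[g].concentration is None for g in used_genes
    )
    if pool_needed:
        ec.add_metabolite(Metabolite(POOL_MET, compartment=ENZYME_COMPARTMENT))
        ec.add_reaction(
            Reaction(
                POOL_EXCHANGE,
                {POOL_MET: 1.0},
                name="protein pool supply",
                lower_bound=0.0,
                upper_bound=pool.capacity,
                subsystem="enzyme",
            )
        )
        parent_map[POOL_EXCHANGE] = (POOL_EXCHANGE, 1.0)

    usage: Dict[str, str] = {}
    for gene in used_genes:
        enz = enzyme_by_gene[gene]
        draw_id = f"draw_prot_{gene}"
        if enz.concentration is not None:
            stoich = {f"prot_{gene}": 1.0}
            ub = enz.concentration
        else:
            stoich = {POOL_MET: -enz.molecular_weight, f"prot_{gene}": 1.0}
            ub = DEFAULT_UPPER
        ec.add_reaction(
            Reaction(
                draw_id,
                stoich,
                name=f"usage of enzyme {gene}",
                lower_bound=0.0,
                upper_bound=ub,
                subsystem="enzyme",
            )
        )
        parent_map[draw_id] = (draw_id, 1.0)
        usage[gene] = draw_id

    return ECModel(
        model=ec,
        parent_map=parent_map,
        usage_reactions=usage,
        enzymes={g: enzyme_by_gene[g] for g in used_genes},
        kcats=ec_kcats,
        pool=pool,
    )


@dataclass
class ParsimoniousSolution(FluxDistribution):
    """Two-stage solution: growth-optimal fluxes with minimal enzyme mass."""

    protein_mass: float = 0.0  # Σ MW_i · e_i at the solution, g·gDW⁻¹


def simulate_parsimonious(ec: ECModel, medium: Medium) -> ParsimoniousSolution:
    """Maximize growth, then minimize total MW-weighted enzyme usage at that
    growth (parsimonious protocol).  Raises ``Infeasible`` for an infeasible
    medium."""
    model = apply_medium(ec.model, medium)
    growth = fba(model).objective_value
    pin = [({model.objective: 1.0}, growth)]
    weights = {
        rid: ec.enzymes[g].molecular_weight for g, rid in ec.usage_reactions.items()
    }
    if weights:
        sol = optimize(model, weights, "min", extra_equalities=pin)
        fluxes = sol.fluxes
        protein = sol.objective_value
    else:
        fluxes = fba(model).fluxes
        protein = 0.0
    return ParsimoniousSolution(
        fluxes=fluxes, objective_value=growth, protein_mass=protein
    )


@dataclass
class FCCResult:
    """Flux control coefficients of every enzyme over one target flux."""

    coefficients: Dict[str, float]
    target: str
    perturbation: float
    base_flux: float
    undefined: bool = False  # base flux was zero; coefficients are meaningless


def _scale_enzyme_kcats(ec: ECModel, gene: str, factor: float) -> ECModel:
    """Return a copy of ``ec`` with every kcat of ``gene`` multiplied by
    ``factor`` (i.e. coupling coefficients divided by it)."""
    out = ec.copy()
    species = f"prot_{gene}"
    for rxn in out.model.reactions:
        if species in rxn.stoichiometry and rxn.stoichiometry[species] < 0:
            rxn.stoichiometry[species] /= factor
    out.kcats = {
        key: (k * factor if key[1] == gene else k) for key, k in ec.kcats.items()
    }
    return out


def flux_control_coefficients(
    ec: ECModel,
    target: Optional[str] = None,
    perturbation: float = 0.001,
    medium: Optional[Medium] = None,
) -> FCCResult:
    """Per-enzyme flux control coefficients over ``target`` (default: the
    model objective).

    For each enzyme all its kcats are scaled by (1 + δ), the target flux is
    re-optimized, and FCC = ((v_up − v_b)/v_b)/δ with δ = ``perturbation``
    (0.001, i.e. a 0.1% kcat increase, by default).  A zero base flux makes
    every ratio undefined; the result is flagged rather than reported as 0.
    """
    target = target or ec.model.objective
    base_model = apply_medium(ec.model, medium) if medium is not None else ec.model
    v_b = fba(base_model, target).objective_value
    if v_b == 0:
        return FCCResult({}, target, perturbation, 0.0, undefined=True)
    coefficients: Dict[str, float] = {}
    for gene in sorted(ec.usage_reactions):
        bumped = _scale_enzyme_kcats(ec, gene, 1.0 + perturbation)
        model = apply_medium(bumped.model, medium) if medium is not None else bumped.model
        v_up = fba(model, target).objective_value
        coefficients[gene] = ((v_up - v_b) / v_b) / perturbation
    return FCCResult(coefficients, target, perturbation, v_b)


def ec_fva_compare(
    model: Model,
    ec: ECModel,
    medium: Medium,
    reactions: Optional[Sequence[str]] = None,
) -> Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]]:
    """Flux variability of the base model versus the enzyme-constrained model
    at the same growth phenotype.

    The ec model is solved parsimoniously on ``medium``; its optimal growth is
    then fixed in both models, and in the base model the uptake of every
    medium substrate is additionally capped at the ec-optimal uptake rate so
    both models describe the same physiology.  Ranges of ec reaction copies
    are reported on the parent namespace (net flux over copies).
    """
    sol = simulate_parsimonious(ec, medium)
    growth = sol.objective_value
    parent_fluxes = ec.project(sol.fluxes)

    targets = list(reactions) if reactions is not None else [r.id for r in model.reactions]

    # Base model: same medium, uptake capped at the ec-optimal uptake.
    base = apply_medium(model, medium)
    for rid in medium:
        uptake = parent_fluxes.get(rid, 0.0)
        base.get_reaction(rid).lower_bound = min(uptake, 0.0)
    pin_base = [({base.objective: 1.0}, growth)]
    try:
        optimize(base, {base.objective: 1.0}, "max", extra_equalities=pin_base)
    except Infeasible as exc:
        raise Infeasible(
            f"ec-optimal growth {growth:.6g} is infeasible in the base model "
            f"with uptake capped at the ec optimum"
        ) from exc

    ec_med = apply_medium(ec.model, medium)
    pin_ec = [({ec_med.objective: 1.0}, growth)]

    result: Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]] = {}
    for rid in targets:
        lo_b = optimize(base, {rid: 1.0}, "min", extra_equalities=pin_base).objective_value
        hi_b = optimize(base, {rid: 1.0}, "max", extra_equalities=pin_base).objective_value
        net = {cid: sign for cid, sign in ec.copies_of(rid)}
        if not net:
            result[rid] = ((lo_b, hi_b), (0.0, 0.0))
            continue
        lo_e = optimize(ec_med, net, "min", extra_equalities=pin_ec).objective_value
        hi_e = optimize(ec_med, net, "max", extra_equalities=pin_ec).objective_value
        result[rid] = ((lo_b, hi_b), (lo_e, hi_e))
    return result
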