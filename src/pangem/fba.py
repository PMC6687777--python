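"""Flux balance analysis (FBA) and flux variability analysis (FVA).

Both are linear programs over the steady-state polytope
{v : S·v = 0, lb ≤ v ≤ ub}; they are solved with the HiGHS solver behind
``scipy.optimize.linprog``.  FBA maximizes (or minimizes) one linear flux
objective; FVA fixes the objective at a given value and reports the
per-reaction attainable flux range.

Infeasibility and unboundedness are reported through dedicated exception
types so callers can distinguish them from genuine numerical failures.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import FluxDistribution, Model

__all__ = [
    "Infeasible",
    "Unbounded",
    "SolverError",
    "fba",
    "fva",
    "optimize",
    "find_dead_ends",
    "check_mass_balance",
]

FEASIBILITY_TOL = 1e-6
OPTIMALITY_TOL = 1e-9


class Infeasible(Exception):
    """The LP has no feasible steady-state flux vector."""


class Unbounded(Exception):
    """The objective is unbounded in the requested direction."""


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasible/unbounded."""


def _build_problem(model: Model):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(coef)
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return S, lb, ub, rxn_index


def optimize(
    model: Model,
    objective: Mapping[str, float],
    direction: str = "max",
    extra_equalities: Sequence[Tuple[Mapping[str, float], float]] = (),
) -> FluxDistribution:
    """Optimize an arbitrary linear flux objective at steady state.

    ``objective`` maps reaction ids to coefficients; ``extra_equalities`` adds
    rows of the form Σ cᵣ·vᵣ = rhs (used to pin a prior optimum during FVA and
    two-stage parsimonious solves).
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    S, lb, ub, rxn_index = _build_problem(model)
    n = len(model.reactions)
    c = np.zeros(n)
    for rid, coef in objective.items():
        c[rxn_index[rid]] += coef
    sign = -1.0 if direction == "max" else 1.0

    b_eq = np.zeros(S.shape[0])
    if extra_equalities:
        extra_rows = sparse.lil_matrix((len(extra_equalities), n))
        extra_rhs = []
        for i, (coefs, rhs) in enumerate(extra_equalities):
            for rid, coef in coefs.items():
                extra_rows[i, rxn_index[rid]] = coef
            extra_rhs.append(rhs)
        A_eq = sparse.vstack([S, extra_rows.tocsr()], format="csr")
        b_eq = np.concatenate([b_eq, extra_rhs])
    else:
        A_eq = S

    res = linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL * 1e-3,
            "dual_feasibility_tolerance": OPTIMALITY_TOL,
        },
    )
    if res.status == 2:
        raise Infeasible(f"model {model.id!r}: no feasible flux distribution")
    if res.status == 3:
        raise Unbounded(f"model {model.id!r}: objective unbounded ({direction})")
    if res.status != 0:
        raise SolverError(f"LP solver failure: {res.message}")
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    obj = float(sum(coef * fluxes[rid] for rid, coef in objective.items()))
    return FluxDistribution(fluxes=fluxes, objective_value=obj)


def fba(
    model: Model, objective: Optional[str] = None, direction: str = "max"
) -> FluxDistribution:
    """Maximize (or minimize) the flux through one reaction at steady state."""
    objective = objective or model.objective
    if objective is None:
        raise ValueError("no objective reaction given and model has none")
    model.get_reaction(objective)  # KeyError for unknown ids
    return optimize(model, {objective: 1.0}, direction)


def fva(
    model: Model,
    fix_objective_at: float,
    objective: Optional[str] = None,
    reactions: Optional[Sequence[str]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux ranges with the objective pinned at a given value."""
    objective = objective or model.objective
    pin = [({objective: 1.0}, fix_objective_at)]
    # One probe solve so an infeasible pin fails fast with the right signal.
    optimize(model, {objective: 1.0}, "max", extra_equalities=pin)
    targets = list(reactions) if reactions is not None else model.reaction_ids
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        lo = optimize(model, {rid: 1.0}, "min", extra_equalities=pin).objective_value
        hi = optimize(model, {rid: 1.0}, "max", extra_equalities=pin).objective_value
        ranges[rid] = (lo, hi)
    return ranges


def find_dead_ends(model: Model) -> set:
    """Metabolites that cannot carry net steady-state flux for connectivity reasons.

    A metabolite is a dead end when no pair of *distinct* reactions can
    respectively produce and consume it, taking reversibility into account.
    This covers the classic only-produced / only-consumed cases and also
    metabolites that touch a single reversible reaction only: one reaction
    carries one net flux, so it cannot act as producer and consumer at once.
    """
    producers: Dict[str, set] = {m.id: set() for m in model.metabolites}
    consumers: Dict[str, set] = {m.id: set() for m in model.metabolites}
    for rxn in model.reactions:
        forward = rxn.upper_bound > 0
        backward = rxn.lower_bound < 0
        for met_id, coef in rxn.stoichiometry.items():
            if coef > 0:
                if forward:
                    producers[met_id].add(rxn.id)
                if backward:
                    consumers[met_id].add(rxn.id)
            elif coef < 0:
                if forward:
                    consumers[met_id].add(rxn.id)
                if backward:
                    producers[met_id].add(rxn.id)
    dead = set()
    for met in model.metabolites:
        prod, cons = producers[met.id], consumers[met.id]
        if not any(p != c for p in prod for c in cons):
            dead.add(met.id)
    return dead


def check_mass_balance(model: Model, tol: float = 1e-6):
    """Elemental balance report for every non-exchange reaction.

    Returns a list of ``(reaction_id, element, imbalance)`` rows; reactions
    touching a metabolite with no formula are reported once as
    ``(reaction_id, "unverifiable", nan)`` instead of being treated as errors.
    Exchange reactions are skipped by construction (they are net element
    sources/sinks).
    """
    report = []
    formulas = {m.id: m.formula for m in model.metabolites}
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        if any(formulas[mid] is None for mid in rxn.stoichiometry):
            report.append((rxn.id, "unverifiable", float("nan")))
            continue
        totals: Dict[str, float] = {}
        for mid, coef in rxn.stoichiometry.items():
            for element, count in formulas[mid].items():
                totals[element] = totals.get(element, 0.0) + coef * count
        for element in sorted(totals):
            if abs(totals[element]) > tol:
                report.append((rxn.id, element, totals[element]))
    return report
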