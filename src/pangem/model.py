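"""Core constraint-based model data structures.

The container mirrors the standard genome-scale metabolic model (GEM)
structure: metabolites with elemental formulas, reactions with signed
stoichiometry, flux bounds in mmol·gDW⁻¹·h⁻¹ and a GPR rule, a gene set, and
one objective reaction (biomass by convention).

Sign conventions follow the field: an exchange reaction is written
``met ↔ ∅`` with a single metabolite at coefficient −1, so uptake is negative
flux and a medium's uptake magnitudes are applied as negative lower bounds.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

from .gpr import GPRExpression, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "Model",
    "Medium",
    "FluxDistribution",
    "ModelError",
    "parse_formula",
    "format_formula",
    "apply_medium",
]

DEFAULT_UPPER = 1000.0
DEFAULT_LOWER = -1000.0

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelError(ValueError):
    """Structural problem in a model definition."""


def parse_formula(text: str) -> Dict[str, float]:
    """Parse an elemental formula string like ``C6H12O6`` into a count map."""
    if not text:
        return {}
    counts: Dict[str, float] = {}
    consumed = 0
    for element, num in _FORMULA_RE.findall(text):
        counts[element] = counts.get(element, 0.0) + (float(num) if num else 1.0)
        consumed += len(element) + len(num)
    if consumed != len(text):
        raise ModelError(f"unparseable formula {text!r}")
    return counts


def format_formula(counts: Mapping[str, float]) -> str:
    def fmt(n: float) -> str:
        if n == 1:
            return ""
        return str(int(n)) if float(n).is_integer() else str(n)

    return "".join(f"{el}{fmt(n)}" for el, n in sorted(counts.items()))


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[Dict[str, float]] = None
    charge: int = 0

    def __post_init__(self):
        if not self.compartment:
            raise ModelError(f"metabolite {self.id!r} has an empty compartment")
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER
    gpr: GPRExpression = field(default_factory=GPRExpression)
    subsystem: str = ""

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions carry exactly one metabolite (``met ↔ ∅``)."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        r = _copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


class Model:
    """A genome-scale metabolic model (stoichiometric network + GPRs)."""

    def __init__(
        self,
        id: str,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        genes: Optional[Iterable[str]] = None,
        objective: Optional[str] = None,
    ):
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        if genes is None:
            genes = set()
            for rxn in self.reactions:
                genes |= rxn.gpr.genes()
        self.genes = set(genes)
        self.objective = objective

    # -- lookup -----------------------------------------------------------
    @property
    def metabolite_ids(self):
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self):
        return [r.id for r in self.reactions]

    def get_metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- mutation ---------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if any(m.id == met.id for m in self.metabolites):
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if any(r.id == rxn.id for r in self.reactions):
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        known = {m.id for m in self.metabolites}
        missing = set(rxn.stoichiometry) - known
        if missing:
            raise ModelError(
                f"reaction {rxn.id!r} references unknown metabolites {sorted(missing)}"
            )
        self.reactions.append(rxn)
        self.genes |= rxn.gpr.genes()

    def copy(self) -> "Model":
        return Model(
            self.id,
            [_copy.copy(m) for m in self.metabolites],
            [r.copy() for r in self.reactions],
            set(self.genes),
            self.objective,
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ``ModelError`` on violation."""
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolites {sorted(missing)}"
                )
            stray = rxn.gpr.genes() - self.genes
            if stray:
                raise ModelError(
                    f"reaction {rxn.id!r} GPR uses genes not in the model: {sorted(stray)}"
                )
        if self.objective is not None and self.objective not in set(rxn_ids):
            raise ModelError(f"objective {self.objective!r} is not a reaction id")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Model {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


class Medium(dict):
    """Maximum uptake rates (positive magnitudes) keyed by exchange reaction id.

    Applying a medium opens the listed exchanges for uptake at ``-rate`` lower
    bound and closes uptake through every other exchange (secretion bounds are
    left untouched), matching the usual minimal-medium convention.
    """

    def validate_against(self, model: Model) -> None:
        for rid in self:
            rxn = model.get_reaction(rid)
            if not rxn.is_exchange:
                raise ModelError(f"medium entry {rid!r} is not an exchange reaction")


def apply_medium(model: Model, medium: Medium) -> Model:
    """Return a copy of ``model`` with uptake bounds set from ``medium``."""
    medium.validate_against(model)
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in medium:
            rate = float(medium[rxn.id])
            if rate < 0:
                raise ModelError(f"medium rate for {rxn.id!r} must be a magnitude")
            rxn.lower_bound = -rate
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out


@dataclass
class FluxDistribution:
    """A steady-state flux vector together with its objective value."""

    fluxes: Dict[str, float]
    objective_value: float

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def get(self, rxn_id: str, default: float = 0.0) -> float:
        return self.fluxes.get(rxn_id, default)
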