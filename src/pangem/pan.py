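"""Pan-model construction, strain-specific model carving, core intersection.

A pan-model is the union of metabolic capabilities across a species' strains:
the reference model with ortholog genes merged into the GPR rules plus any
new reactions contributed by non-reference genes.  A strain-specific model is
carved from the pan-model using the strain's gene presence: a reaction is
kept iff its GPR still evaluates true (a missing complex subunit removes the
reaction, a missing isoenzyme merely shrinks the rule).  The core model is
the element-wise (id-level) intersection of a collection of strain models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .gpr import GPRExpression, evaluate_gpr, prune_gpr
from .model import Model, ModelError, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologEntry",
    "PresenceMatrix",
    "merge_ortholog_gpr",
    "build_pan_model",
    "carve_strain",
    "carve_all",
    "build_core",
    "CoreResult",
]


@dataclass(frozen=True)
class OrthologEntry:
    """An ortholog (pan-genome gene) of a reference-model gene."""

    reference_gene: str
    ortholog_gene: str
    identity: float  # sequence identity fraction in [0, 1]

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity must be in [0,1], got {self.identity}")


class PresenceMatrix:
    """Strains × pan-genes 0/1 matrix driving strain carving."""

    def __init__(self, strains: Sequence[str], genes: Sequence[str], values):
        self.strains = list(strains)
        self.genes = list(genes)
        self.values = np.asarray(values, dtype=int)
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain ids")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if self.values.shape != (len(self.strains), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.strains)} strains × {len(self.genes)} genes"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence values must be strictly 0/1")

    def present_genes(self, strain: str) -> Set[str]:
        row = self.values[self.strains.index(strain)]
        return {g for g, v in zip(self.genes, row) if v}

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.values)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.strains, columns=self.genes).to_csv(
            path, sep="\t", index_label="strain"
        )


def merge_ortholog_gpr(
    expr: GPRExpression, reference: str, ortholog: str
) -> GPRExpression:
    """Add ``ortholog`` as a functional alternative of ``reference`` in a GPR.

    An isoenzyme reference (OR-level alternative, e.g. ``A or B``) gains the
    ortholog as one more alternative (``A or B or C``); a complex subunit
    (inside an AND clause, e.g. ``A and B``) duplicates the whole clause with
    the reference replaced (``(A and B) or (C and B)``).  Applied to every
    occurrence of the reference.
    """
    if reference not in expr.genes():
        raise ModelError(
            f"reference gene {reference!r} not in GPR {expr.to_string()!r}"
        )
    from .gpr import _flatten  # tree utilities share the gpr module's format

    def walk(node):
        if isinstance(node, str):
            if node == reference:
                return _flatten("or", [node, ortholog])
            return node
        op, children = node
        if op == "or":
            new_children: List = []
            add_alt = False
            for child in children:
                if isinstance(child, str) and child == reference:
                    new_children.append(child)
                    add_alt = True  # append the ortholog at the end of the OR
                else:
                    new_children.append(walk(child))
            if add_alt:
                new_children.append(ortholog)
            return _flatten("or", new_children)
        # AND clause: duplicate the clause with the reference substituted.
        if reference in GPRExpression(node).genes():
            substituted = GPRExpression(node).substitute({reference: ortholog})
            return _flatten("or", [node, substituted.root])
        return node

    return GPRExpression(walk(expr.root))


def build_pan_model(
    base: Model,
    orthologs: Iterable[OrthologEntry] = (),
    new_reactions: Iterable[Reaction] = (),
    new_metabolites=(),
    identity_threshold: float = 0.8,
) -> Model:
    """Merge ortholog genes and new reactions into a reference model.

    Orthologs below ``identity_threshold`` or referencing an absent gene are
    skipped with a log message; no reaction of the base model is ever
    removed.
    """
    pan = base.copy()
    pan.id = f"pan_{base.id}"
    for entry in orthologs:
        if entry.identity < identity_threshold:
            logger.info(
                "ortholog %s→%s skipped: identity %.3f below threshold %.2f",
                entry.reference_gene,
                entry.ortholog_gene,
                entry.identity,
                identity_threshold,
            )
            continue
        if entry.reference_gene not in pan.genes:
            logger.warning(
                "ortholog %s skipped: reference gene %s absent from the model",
                entry.ortholog_gene,
                entry.reference_gene,
            )
            continue
        for rxn in pan.reactions:
            if entry.reference_gene in rxn.gpr.genes():
                rxn.gpr = merge_ortholog_gpr(
                    rxn.gpr, entry.reference_gene, entry.ortholog_gene
                )
        pan.genes.add(entry.ortholog_gene)
    for met in new_metabolites:
        pan.add_metabolite(met)
    for rxn in new_reactions:
        pan.add_reaction(rxn)  # raises on duplicate ids / unknown metabolites
    pan.validate()
    return pan


def carve_strain(
    pan: Model,
    present: Iterable[str],
    strain_id: Optional[str] = None,
    keep_orphans: bool = False,
    gene_translation: Optional[Mapping[str, str]] = None,
) -> Model:
    """Carve a strain-specific model out of the pan-model.

    A reaction survives iff its GPR evaluates true over ``present`` (empty
    GPRs — spontaneous reactions, exchanges, pseudo-reactions — always
    survive); surviving GPRs are pruned to the present genes.  Metabolites no
    longer referenced by any reaction are dropped unless ``keep_orphans``.
    ``gene_translation`` renames presence-list ids onto model ids before
    carving (collapsed pan-genome ids).
    """
    present = set(present)
    if gene_translation:
        present = {gene_translation.get(g, g) for g in present}
    unknown = present - pan.genes
    if unknown:
        logger.info("%d presence ids not in the pan-model; ignored", len(unknown))
        present &= pan.genes
    kept: List[Reaction] = []
    for rxn in pan.reactions:
        if evaluate_gpr(rxn.gpr, present):
            new = rxn.copy()
            new.gpr = prune_gpr(rxn.gpr, present)
            kept.append(new)
    used_mets = set()
    for rxn in kept:
        used_mets |= set(rxn.stoichiometry)
    mets = [
        m for m in pan.metabolites if keep_orphans or m.id in used_mets
    ]
    used_genes = set()
    for rxn in kept:
        used_genes |= rxn.gpr.genes()
    objective = pan.objective if any(r.id == pan.objective for r in kept) else None
    # After pruning, every GPR leaf is present, so the gene set is exactly the
    # genes still doing work: present ∩ (genes used by retained reactions).
    return Model(strain_id or f"{pan.id}_carved", mets, kept, used_genes, objective)


def carve_all(pan: Model, matrix: PresenceMatrix) -> Dict[str, Model]:
    """Carve one model per strain of a presence matrix (deterministic order)."""
    if not matrix.strains:
        raise ValueError("presence matrix has no strains")
    missing = set(matrix.genes) - pan.genes
    if missing:
        logger.info("%d matrix genes absent from the pan-model; ignored", len(missing))
    return {
        strain: carve_strain(pan, matrix.present_genes(strain), strain_id=strain)
        for strain in matrix.strains
    }


def carve_summary(models: Mapping[str, Model]) -> pd.DataFrame:
    """Per-strain counts of reactions, metabolites and genes."""
    return pd.DataFrame(
        {
            "strain": list(models),
            "reactions": [len(m.reactions) for m in models.values()],
            "metabolites": [len(m.metabolites) for m in models.values()],
            "genes": [len(m.genes) for m in models.values()],
        }
    ).set_index("strain")


@dataclass
class CoreResult:
    """Core model plus the elements that vary across the input models."""

    core: Model
    variable_reactions: Set[str]
    variable_genes: Set[str]
    variable_metabolites: Set[str]


def build_core(models: Iterable[Model], id: str = "core") -> CoreResult:
    """Intersect ≥ 2 models sharing a namespace into a core model.

    The core keeps exactly the reactions, genes and metabolites present (by
    id) in every input model; everything else is reported as variable.
    Reaction/metabolite definitions are taken from the first model (the
    shared-namespace assumption of pan-derived models).
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two models to intersect")
    first = models[0]
    rxn_sets = [set(m.reaction_ids) for m in models]
    met_sets = [set(m.metabolite_ids) for m in models]
    gene_sets = [set(m.genes) for m in models]
    core_rxns = set.intersection(*rxn_sets)
    core_mets = set.intersection(*met_sets)
    core_genes = set.intersection(*gene_sets)
    reactions = []
    for rxn in first.reactions:
        if rxn.id not in core_rxns:
            continue
        new = rxn.copy()
        # The rule itself may differ across strains after pruning; restrict
        # it to core genes when possible, otherwise keep the first model's.
        if evaluate_gpr(new.gpr, core_genes):
            new.gpr = prune_gpr(new.gpr, core_genes)
        reactions.append(new)
    used = set()
    for rxn in reactions:
        used |= set(rxn.stoichiometry)
    mets = [m for m in first.metabolites if m.id in (core_mets | used)]
    objective = first.objective if first.objective in core_rxns else None
    # The gene set is the exact intersection; a reaction whose (isoenzyme)
    # rule still names a variable gene keeps it in the rule only.
    core = Model(id, mets, reactions, set(core_genes), objective)
    return CoreResult(
        core=core,
        variable_reactions=set.union(*rxn_sets) - core_rxns,
        variable_genes=set.union(*gene_sets) - core_genes,
        variable_metabolites=set.union(*met_sets) - core_mets,
    )
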