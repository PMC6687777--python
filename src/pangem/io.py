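"""Model readers and writers.

Two formats are supported:

* SBML Level 3 with the FBC package (flux bounds + gene associations),
  delegated to cobrapy/libsbml.  Constructs outside the constraint-based
  subset (kinetic laws, events, ...) are ignored by the reader with a logged
  warning, which matches how the field's tooling treats them.
* A three-file TSV dialect (``metabolites.tsv``, ``reactions.tsv``,
  ``genes.tsv`` in one directory) that is diff-friendly and used by the
  synthetic fixtures.  Stoichiometry is encoded ``met_id:coef;met_id:coef``
  and GPRs as infix text.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Union

import pandas as pd

from .gpr import parse_gpr
from .model import Metabolite, Model, ModelError, Reaction, format_formula

logger = logging.getLogger(__name__)

__all__ = ["load_model", "save_model", "to_cobra", "from_cobra"]


# ---------------------------------------------------------------------------
# cobra bridge (SBML)
# ---------------------------------------------------------------------------

def to_cobra(model: Model):
    """Convert to a cobrapy model (used for SBML serialization and as an
    independent solver route)."""
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {}
    for met in model.metabolites:
        cm = cobra.Metabolite(
            met.id,
            name=met.name,
            compartment=met.compartment,
            charge=met.charge,
            formula=format_formula(met.formula) if met.formula else None,
        )
        cmets[met.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for rxn in model.reactions:
        cr = cobra.Reaction(
            rxn.id,
            name=rxn.name,
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        cr.subsystem = rxn.subsystem
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for rxn, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[mid]: coef for mid, coef in rxn.stoichiometry.items()})
        cr.gene_reaction_rule = rxn.gpr.to_string()
    if model.objective is not None:
        cmodel.objective = model.objective
    return cmodel


def from_cobra(cmodel) -> Model:
    from cobra.util.solver import linear_reaction_coefficients

    mets = [
        Metabolite(
            m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            formula=m.formula or None,
            charge=int(m.charge) if m.charge is not None else 0,
        )
        for m in cmodel.metabolites
    ]
    rxns = [
        Reaction(
            r.id,
            {m.id: coef for m, coef in r.metabolites.items()},
            name=r.name or "",
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=parse_gpr(r.gene_reaction_rule or ""),
            subsystem=r.subsystem or "",
        )
        for r in cmodel.reactions
    ]
    objective = None
    coefs = linear_reaction_coefficients(cmodel)
    if coefs:
        objective = next(iter(coefs)).id
    return Model(cmodel.id or "model", mets, rxns, objective=objective)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _stoich_to_text(stoich) -> str:
    return ";".join(f"{mid}:{coef:g}" for mid, coef in stoich.items())


def _stoich_from_text(text: str):
    out = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        mid, _, coef = part.rpartition(":")
        if not mid:
            raise ModelError(f"bad stoichiometry entry {part!r}")
        out[mid] = float(coef)
    return out


def _save_tsv(model: Model, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
            "formula": [format_formula(m.formula) if m.formula else "" for m in model.metabolites],
            "charge": [m.charge for m in model.metabolites],
        }
    ).to_csv(directory / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "name": [r.name for r in model.reactions],
            "stoichiometry": [_stoich_to_text(r.stoichiometry) for r in model.reactions],
            "lower_bound": [r.lower_bound for r in model.reactions],
            "upper_bound": [r.upper_bound for r in model.reactions],
            "gpr": [r.gpr.to_string() for r in model.reactions],
            "subsystem": [r.subsystem for r in model.reactions],
            "objective": [int(r.id == model.objective) for r in model.reactions],
        }
    ).to_csv(directory / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": sorted(model.genes)}).to_csv(
        directory / "genes.tsv", sep="\t", index=False
    )


def _load_tsv(directory: Path) -> Model:
    mets_df = pd.read_csv(directory / "metabolites.tsv", sep="\t", keep_default_na=False)
    rxns_df = pd.read_csv(directory / "reactions.tsv", sep="\t", keep_default_na=False)
    mets = [
        Metabolite(
            str(row["id"]),
            name=str(row.get("name", "")),
            compartment=str(row.get("compartment", "c")),
            formula=str(row.get("formula", "")) or None,
            charge=int(row["charge"]) if str(row.get("charge", "")) != "" else 0,
        )
        for _, row in mets_df.iterrows()
    ]
    rxns, objective = [], None
    for _, row in rxns_df.iterrows():
        rxn = Reaction(
            str(row["id"]),
            _stoich_from_text(row["stoichiometry"]),
            name=str(row.get("name", "")),
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            gpr=parse_gpr(str(row.get("gpr", ""))),
            subsystem=str(row.get("subsystem", "")),
        )
        rxns.append(rxn)
        if "objective" in rxns_df.columns and int(row["objective"]):
            objective = rxn.id
    genes = None
    genes_path = directory / "genes.tsv"
    if genes_path.exists():
        gdf = pd.read_csv(genes_path, sep="\t", keep_default_na=False)
        genes = set(str(g) for g in gdf["gene_id"])
    model = Model(directory.name or "model", mets, rxns, genes=genes, objective=objective)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def save_model(model: Model, path: Union[str, Path]) -> None:
    """Write a model as SBML (``.xml``) or the TSV dialect (a directory)."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        import cobra

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        _save_tsv(model, path)


def load_model(path: Union[str, Path]) -> Model:
    """Read a model from SBML (``.xml``) or the TSV dialect directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no model at {path}")
    if path.is_dir():
        return _load_tsv(path)
    if path.suffix.lower() == ".xml":
        import cobra

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cmodel = cobra.io.read_sbml_model(str(path))
        for w in caught:
            logger.warning("SBML reader: %s", w.message)
        return from_cobra(cmodel)
    raise ModelError(f"unrecognized model format: {path}")
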