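"""Protein structure models: Cα coordinates, quality control, domain mapping.

A structure model holds the Cα trace of one protein chain over a covered
residue interval, together with the quality metadata used to decide whether
the structure is reliable enough for mutation mapping: QMEAN, sequence
identity (SI) and similarity (SS) for homology models, resolution and exact
sequence agreement for experimental structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "HOMOLOGY_THRESHOLDS",
    "filter_structures",
    "quality_cutoff_from_distribution",
    "assign_domains",
    "read_ca_pdb",
    "write_ca_pdb",
    "load_structure_table",
]

# Homology models must satisfy all four; experimental structures must have
# perfect sequence identity, resolution ≤ 3.4 Å and no internal gaps.
HOMOLOGY_THRESHOLDS = {
    "qmean_min": -4.0,
    "identity_min": 0.25,
    "similarity_min": 0.31,
    "resolution_max": 3.4,
}
EXPERIMENTAL_RESOLUTION_MAX = 3.4


@dataclass
class StructureModel:
    protein_id: str
    source: str  # "experimental" | "homology"
    coverage: Tuple[int, int]  # first and last covered residue, 1-based
    coordinates: np.ndarray  # (n_covered, 3) Cα positions in Å
    qmean: Optional[float] = None
    identity: Optional[float] = None  # fraction
    similarity: Optional[float] = None  # fraction
    resolution: Optional[float] = None  # Å
    template: str = ""
    chain: str = "A"
    has_gaps: bool = False

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        first, last = self.coverage
        if first < 1 or last < first:
            raise ValueError(f"bad coverage interval {self.coverage}")
        if self.source not in ("experimental", "homology"):
            raise ValueError(f"unknown structure source {self.source!r}")
        if self.coordinates.shape != (last - first + 1, 3):
            raise ValueError(
                f"{self.protein_id}: {self.coordinates.shape[0]} coordinates for "
                f"coverage {first}-{last}"
            )

    @property
    def covered_residues(self) -> range:
        return range(self.coverage[0], self.coverage[1] + 1)

    def covers(self, residue: int) -> bool:
        return self.coverage[0] <= residue <= self.coverage[1]

    def residue_coords(self, residues: Sequence[int]) -> np.ndarray:
        idx = np.asarray(residues, dtype=int) - self.coverage[0]
        if (idx < 0).any() or (idx >= len(self.coordinates)).any():
            raise KeyError("residue outside the covered interval")
        return self.coordinates[idx]


def filter_structures(
    entries: Iterable[StructureModel],
) -> Tuple[List[StructureModel], List[Tuple[StructureModel, str]]]:
    """Split structures into quality-passing and rejected-with-reason.

    Homology models: QMEAN ≥ −4, SI ≥ 0.25, SS ≥ 0.31, resolution ≤ 3.4 Å
    (all inclusive).  Experimental: sequence identity exactly 100%,
    resolution ≤ 3.4 Å, no internal sequence gaps.  Missing metrics count as
    failures of their criterion.
    """
    kept: List[StructureModel] = []
    rejected: List[Tuple[StructureModel, str]] = []
    for entry in entries:
        reason = _rejection_reason(entry)
        if reason is None:
            kept.append(entry)
        else:
            rejected.append((entry, reason))
    return kept, rejected


def _rejection_reason(entry: StructureModel) -> Optional[str]:
    t = HOMOLOGY_THRESHOLDS
    if entry.source == "homology":
        if entry.qmean is None or entry.qmean < t["qmean_min"]:
            return f"QMEAN < {t['qmean_min']}"
        if entry.identity is None or entry.identity < t["identity_min"]:
            return f"sequence identity < {t['identity_min']}"
        if entry.similarity is None or entry.similarity < t["similarity_min"]:
            return f"sequence similarity < {t['similarity_min']}"
        if entry.resolution is not None and entry.resolution > t["resolution_max"]:
            return f"resolution > {t['resolution_max']} Å"
        return None
    if entry.identity is None or entry.identity != 1.0:
        return "sequence identity ≠ 100%"
    if entry.resolution is None or entry.resolution > EXPERIMENTAL_RESOLUTION_MAX:
        return f"resolution > {EXPERIMENTAL_RESOLUTION_MAX} Å"
    if entry.has_gaps:
        return "internal sequence gaps"
    return None


def quality_cutoff_from_distribution(
    values: Sequence[float], tail: str = "lower", p: float = 0.1
) -> float:
    """Normal-approximation quality cutoff at tail probability ``p``.

    Fits a normal by sample mean and SD and returns mean − z₁₋ₚ·SD (lower
    tail) or mean + z₁₋ₚ·SD (upper tail); at p = 0.1, z₁₋ₚ ≈ 1.2816.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3 or not np.isfinite(values).all():
        raise ValueError("need at least 3 finite values")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        logger.warning("zero variance; cutoff equals the mean")
        return mean
    z = float(norm.ppf(1.0 - p))
    return mean - z * sd if tail == "lower" else mean + z * sd


def assign_domains(
    domains: Iterable[Tuple[str, int, int, str]],
    structures: Iterable[StructureModel],
) -> Dict[Tuple[str, str], List[StructureModel]]:
    """Assign structures to protein domains they cover completely.

    ``domains`` rows are (protein_id, start, end, domain_name); a structure is
    assigned iff its coverage interval contains [start, end] entirely.
    Returns {(protein_id, domain_name): [structures]} (complete domains only).
    """
    by_protein: Dict[str, List[StructureModel]] = {}
    for s in structures:
        by_protein.setdefault(s.protein_id, []).append(s)
    out: Dict[Tuple[str, str], List[StructureModel]] = {}
    for protein_id, start, end, name in domains:
        if start < 1 or end < start:
            raise ValueError(f"bad domain interval {start}-{end} for {name!r}")
        matches = [
            s
            for s in by_protein.get(protein_id, [])
            if s.coverage[0] <= start and s.coverage[1] >= end
        ]
        if matches:
            out[(protein_id, name)] = matches
    return out


# ---------------------------------------------------------------------------
# PDB I/O (Cα traces)
# ---------------------------------------------------------------------------

def write_ca_pdb(structure: StructureModel, path) -> None:
    """Write the Cα trace as a minimal single-chain PDB file."""
    lines = []
    for i, residue in enumerate(structure.covered_residues):
        x, y, z = structure.coordinates[i]
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA {structure.chain}{residue:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ca_pdb(
    path,
    protein_id: str,
    chain: str = "A",
    source: str = "homology",
    **metadata,
) -> StructureModel:
    """Read the Cα trace of one chain from a PDB file (via Biopython)."""
    import warnings

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate header-less minimal files
        parsed = PDBParser(QUIET=True).get_structure(protein_id, str(path))
    model = next(parsed.get_models())
    residues: Dict[int, np.ndarray] = {}
    for res in model[chain]:
        if "CA" in res:
            residues[res.id[1]] = res["CA"].coord
    if not residues:
        raise ValueError(f"no Cα atoms in chain {chain!r} of {path}")
    first, last = min(residues), max(residues)
    missing = [q for q in range(first, last + 1) if q not in residues]
    if missing:
        raise ValueError(f"chain {chain!r} of {path} has gaps at residues {missing}")
    coords = np.array([residues[q] for q in range(first, last + 1)], dtype=float)
    return StructureModel(
        protein_id=protein_id,
        source=source,
        coverage=(first, last),
        coordinates=coords,
        chain=chain,
        **metadata,
    )


def load_structure_table(tsv_path) -> List[StructureModel]:
    """Load structures listed in a metadata TSV.

    Expected columns: protein_id, source, from_res, to_res, qmean, sid, sim,
    resolution, pdb_path, chain.  PDB paths are resolved relative to the TSV.
    Empty metric cells become None.
    """
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", keep_default_na=False)
    out: List[StructureModel] = []

    def opt(row, col):
        value = str(row.get(col, "")).strip()
        return float(value) if value else None

    for _, row in df.iterrows():
        pdb = Path(str(row["pdb_path"]))
        if not pdb.is_absolute():
            pdb = tsv_path.parent / pdb
        structure = read_ca_pdb(
            pdb,
            protein_id=str(row["protein_id"]),
            chain=str(row.get("chain", "A") or "A"),
            source=str(row["source"]),
            qmean=opt(row, "qmean"),
            identity=opt(row, "sid"),
            similarity=opt(row, "sim"),
            resolution=opt(row, "resolution"),
        )
        expected = (int(row["from_res"]), int(row["to_res"]))
        if structure.coverage != expected:
            raise ValueError(
                f"{row['protein_id']}: PDB covers {structure.coverage}, "
                f"metadata says {expected}"
            )
        out.append(structure)
    return out
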