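"""Seeded synthetic inputs for every pipeline stage.

The generators emulate the *shape* of real inputs — a growing metabolic
network with isoenzymes, complexes, exchanges and a planted dead end; kcat
and enzyme tables; strain gene-presence matrices; Cα traces with controlled
geometry; coding genes on both strands and a multi-sample VCF whose records
straddle every quality-filter threshold — without attempting realistic
genome statistics.  Every generator is a pure function of its arguments and
seed, so repeated calls are byte-identical.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .ecmodel import EnzymeEntry, KcatEntry
from .model import Medium, Metabolite, Model, Reaction
from .pan import PresenceMatrix
from .snp import CDSAnnotation
from .structures import StructureModel

__all__ = [
    "ToySpec",
    "make_toy_gem",
    "minimal_medium",
    "make_kcat_table",
    "make_enzyme_table",
    "make_presence_matrix",
    "make_chain_structure",
    "make_synthetic_genes",
    "make_synthetic_vcf",
]

_SUGAR = {"C": 6, "H": 12, "O": 6}
_TRIOSE = {"C": 3, "H": 6, "O": 3}
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ToySpec:
    """Size knobs of the synthetic ecosystem (all counts ≥ 0)."""

    seed: int = 0
    n_strains: int = 8
    n_isoenzyme_reactions: int = 1
    n_complex_reactions: int = 1
    n_parallel_routes: int = 0  # redundant substrate→precursor routes
    chain_length: int = 60  # residues in synthetic structures
    n_snps: int = 200

    def __post_init__(self):
        if min(self.n_strains, self.n_isoenzyme_reactions,
               self.n_complex_reactions, self.n_parallel_routes,
               self.chain_length, self.n_snps) < 0:
            raise ValueError("all ToySpec counts must be ≥ 0")


def make_toy_gem(spec: ToySpec = ToySpec()) -> Model:
    """A small feasible growth model emulating a GEM's GPR structure.

    Glucose (or fructose via an isomerase) is taken up and converted through
    a chain of isoenzyme-gated and complex-gated steps into a biomass
    precursor; biomass is drained through an exchange.  One irreversible
    side reaction produces a deliberately planted dead-end metabolite.  All
    reactions except the biomass pseudo-reaction are elementally balanced.
    """
    mets = [
        Metabolite("glc_e", "glucose (extracellular)", "e", dict(_SUGAR)),
        Metabolite("glc_c", "glucose", "c", dict(_SUGAR)),
        Metabolite("fru_e", "fructose (extracellular)", "e", dict(_SUGAR)),
        Metabolite("fru_c", "fructose", "c", dict(_SUGAR)),
        Metabolite("aa_c", "biomass precursor", "c", dict(_TRIOSE)),
        Metabolite("biomass_c", "biomass", "c", None),
        Metabolite("dead_c", "planted dead end", "c", dict(_SUGAR)),
    ]
    rxns = [
        Reaction("EX_glc", {"glc_e": -1.0}, "glucose exchange", -10.0, 1000.0),
        Reaction("EX_fru", {"fru_e": -1.0}, "fructose exchange", -1000.0, 1000.0),
        Reaction("EX_biomass", {"biomass_c": -1.0}, "biomass drain", 0.0, 1000.0),
        Reaction("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, "glucose transport",
                 0.0, 1000.0, "g_tglc"),
        Reaction("T_fru", {"fru_e": -1.0, "fru_c": 1.0}, "fructose transport",
                 0.0, 1000.0, "g_tfru"),
        Reaction("R_fiso", {"fru_c": -1.0, "glc_c": 1.0}, "sugar isomerase",
                 0.0, 1000.0, "g_fiso"),
        Reaction("R_dead", {"glc_c": -1.0, "dead_c": 1.0}, "dead-end branch",
                 0.0, 1000.0, "g_dead"),
    ]
    # Chain of gated steps glc_c → ... → pre_aa, isoenzymes first, complexes after.
    previous = "glc_c"
    step = 0
    for k in range(1, spec.n_isoenzyme_reactions + 1):
        step += 1
        nxt = f"m{step}_c"
        mets.append(Metabolite(nxt, f"intermediate {step}", "c", dict(_SUGAR)))
        rxns.append(
            Reaction(f"R_iso{k}", {previous: -1.0, nxt: 1.0},
                     f"isoenzyme step {k}", 0.0, 1000.0, f"gI{k}a or gI{k}b")
        )
        previous = nxt
    for k in range(1, spec.n_complex_reactions + 1):
        step += 1
        nxt = f"m{step}_c"
        mets.append(Metabolite(nxt, f"intermediate {step}", "c", dict(_SUGAR)))
        rxns.append(
            Reaction(f"R_cplx{k}", {previous: -1.0, nxt: 1.0},
                     f"complex step {k}", 0.0, 1000.0, f"gC{k}a and gC{k}b")
        )
        previous = nxt
    rxns.append(
        Reaction("R_aa", {previous: -1.0, "aa_c": 2.0}, "precursor cleavage",
                 0.0, 1000.0, "g_aa")
    )
    # Redundant one-step routes substrate → precursor: these create genuine
    # flux variability at a fixed growth rate in the unconstrained model.
    for k in range(1, spec.n_parallel_routes + 1):
        rxns.append(
            Reaction(f"R_par{k}", {"glc_c": -1.0, "aa_c": 2.0},
                     f"parallel route {k}", 0.0, 1000.0, f"g_par{k}")
        )
    rxns.append(
        Reaction("R_biomass", {"aa_c": -2.0, "biomass_c": 1.0}, "growth",
                 0.0, 1000.0)
    )
    model = Model(f"toy_gem_seed{spec.seed}", mets, rxns, objective="R_biomass")
    model.validate()
    return model


def minimal_medium(model: Model, uptake: float = 10.0) -> Medium:
    """Glucose-only minimal medium for the toy model."""
    return Medium({"EX_glc": uptake})


def make_kcat_table(model: Model, seed: int = 0,
                    kcat_range: Tuple[float, float] = (1e2, 1e4)) -> List[KcatEntry]:
    """Log-uniform kcats (h⁻¹) for every gene of every gene-associated,
    non-exchange reaction."""
    rng = np.random.default_rng(seed)
    lo, hi = math.log(kcat_range[0]), math.log(kcat_range[1])
    out: List[KcatEntry] = []
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.gpr.is_empty:
            continue
        for gene in sorted(rxn.gpr.genes()):
            out.append(KcatEntry(rxn.id, gene, math.exp(rng.uniform(lo, hi))))
    return out


def make_enzyme_table(model: Model, seed: int = 0,
                      mw_range: Tuple[float, float] = (20.0, 120.0),
                      concentration: Optional[float] = None) -> List[EnzymeEntry]:
    """Molecular weights (g·mmol⁻¹) for every gene; optionally one shared
    concentration bound, otherwise pool-limited enzymes."""
    rng = np.random.default_rng(seed)
    return [
        EnzymeEntry(gene, float(rng.uniform(*mw_range)), concentration)
        for gene in sorted(model.genes)
    ]


def make_presence_matrix(
    pan: Model,
    n_strains: int,
    seed: int = 0,
    dropout: float = 0.2,
    nested: bool = False,
    protected: Iterable[str] = (),
) -> PresenceMatrix:
    """Strain × pan-gene 0/1 matrix with one all-present reference strain.

    Non-reference strains lose each unprotected gene independently with
    probability ``dropout``; with ``nested=True`` each strain's gene set is a
    subset of the previous strain's (useful for monotonicity checks).
    """
    if n_strains < 1:
        raise ValueError("need at least one strain")
    rng = np.random.default_rng(seed)
    genes = sorted(pan.genes)
    protected = set(protected)
    values = np.ones((n_strains, len(genes)), dtype=int)
    dropped: Set[str] = set()
    for row in range(1, n_strains):
        if not nested:
            dropped = set()
        for j, gene in enumerate(genes):
            if gene in protected:
                continue
            if gene in dropped or rng.random() < dropout:
                dropped.add(gene)
                values[row, j] = 0
    strains = [f"strain{n:03d}" for n in range(n_strains)]
    return PresenceMatrix(strains, genes, values)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

CA_SPACING = 3.8  # canonical Cα–Cα virtual bond length, Å


def make_chain_structure(
    length: int,
    geometry: str = "extended",
    seed: int = 0,
    protein_id: str = "P1",
) -> StructureModel:
    """Synthetic Cα trace with full coverage and filter-passing metadata.

    ``extended``: straight chain, consecutive spacing 3.8 Å and sequence
    separation proportional to spatial distance.  ``helix``: ideal α-helix
    (2.3 Å radius, 1.5 Å rise, 100°/residue).  ``compact``: a boustrophedon
    walk through a 3D grid, so residues ≥ 20 apart in sequence can sit
    < 10 Å apart in space.
    """
    if length < 2:
        raise ValueError("need at least two residues")
    idx = np.arange(length)
    if geometry == "extended":
        coords = np.column_stack([CA_SPACING * idx, np.zeros(length), np.zeros(length)])
    elif geometry == "helix":
        angle = np.deg2rad(100.0) * idx
        coords = np.column_stack([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * idx])
    elif geometry == "compact":
        side = 10
        col = idx % side
        row = (idx // side) % side
        layer = idx // (side * side)
        eff_col = np.where(row % 2 == 0, col, side - 1 - col)
        eff_row = np.where(layer % 2 == 0, row, side - 1 - row)
        coords = CA_SPACING * np.column_stack([eff_col, eff_row, layer]).astype(float)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return StructureModel(
        protein_id=protein_id,
        source="homology",
        coverage=(1, length),
        coordinates=coords,
        qmean=-1.0,
        identity=0.95,
        similarity=0.97,
        resolution=2.0,
        template=f"synthetic_{geometry}_seed{seed}",
    )


# ---------------------------------------------------------------------------
# genes, genome and VCF
# ---------------------------------------------------------------------------

def _random_cds(rng, protein_length: int) -> str:
    """ATG + non-stop codons + TAA, total (protein_length + 1) codons."""
    codons = ["ATG"]
    sense = [c for c in map("".join, itertools.product(_BASES, repeat=3))
             if c not in _STOPS and c != "ATG"]
    for _ in range(protein_length - 1):
        codons.append(sense[rng.integers(len(sense))])
    codons.append("TAA")
    return "".join(codons)


def make_synthetic_genes(
    seed: int = 0,
    n_genes: int = 4,
    protein_length: int = 60,
    chrom: str = "chr1",
    spacing: int = 120,
) -> Tuple[Dict[str, str], Dict[str, CDSAnnotation]]:
    """A synthetic chromosome with coding genes on both strands.

    Odd-indexed genes go on the minus strand and every second gene is split
    into two exons, exercising strand-aware and spliced coordinate mapping.
    Returns (genome, annotations keyed by gene id).
    """
    rng = np.random.default_rng(seed)
    sequence: List[str] = []
    annotations: Dict[str, CDSAnnotation] = {}
    cursor = 0

    def spacer(n: int) -> None:
        nonlocal cursor
        sequence.append("".join(_BASES[i] for i in rng.integers(0, 4, size=n)))
        cursor += n

    spacer(spacing)
    for g in range(n_genes):
        gene_id = f"G{g + 1:03d}"
        strand = "-" if g % 2 else "+"
        cds = _random_cds(rng, protein_length)
        genomic = str(Seq(cds).reverse_complement()) if strand == "-" else cds
        if g % 2 == 0 and g + 1 < n_genes:  # intron-less gene
            start = cursor + 1
            sequence.append(genomic)
            cursor += len(genomic)
            exons = ((start, cursor),)
        else:  # two exons separated by a short intron
            half = (len(genomic) // 2) // 3 * 3 or 3
            intron_len = 30
            start1 = cursor + 1
            sequence.append(genomic[:half])
            cursor += half
            exon1 = (start1, cursor)
            spacer(intron_len)
            start2 = cursor + 1
            sequence.append(genomic[half:])
            cursor += len(genomic) - half
            exons = (exon1, (start2, cursor))
        # Exon intervals are genomic; for minus-strand genes translation
        # order runs high→low, which CDSAnnotation handles internally.
        annotations[gene_id] = CDSAnnotation(gene_id, chrom, exons, strand)
        spacer(spacing)
    return {chrom: "".join(sequence)}, annotations


def _mutation_truth(
    genome: Mapping[str, str],
    cds: CDSAnnotation,
    pos: int,
    alt: str,
) -> Tuple[str, Optional[int]]:
    """Full-translation oracle: rebuild the mutant CDS and diff the proteins.

    Independent of the per-codon arithmetic in ``snp.classify_snp``.
    """
    seq = genome[cds.chrom]
    mutant = seq[: pos - 1] + alt + seq[pos:]

    def protein(source: str) -> str:
        parts = [source[s - 1 : e] for s, e in cds.exons]
        coding = "".join(parts)
        if cds.strand == "-":
            coding = str(Seq(coding).reverse_complement())
        return str(Seq(coding).translate())

    ref_prot, alt_prot = protein(seq), protein(mutant)
    if ref_prot == alt_prot:
        return "sSNP", _codon_of(cds, pos)
    diff = next(i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b)
    return "nsSNP", diff + 1


def _codon_of(cds: CDSAnnotation, pos: int) -> Optional[int]:
    cds_pos = cds.genomic_to_cds(pos)
    return None if cds_pos is None else (cds_pos - 1) // 3 + 1


def make_synthetic_vcf(
    genes: Mapping[str, CDSAnnotation],
    genome: Mapping[str, str],
    n_snps: int,
    out_vcf,
    seed: int = 0,
    n_strains: int = 6,
    hotspot: Optional[Mapping[str, Sequence[int]]] = None,
    hotspot_fraction: float = 0.5,
) -> pd.DataFrame:
    """Write a multi-sample VCF plus a generator-side truth table.

    Quality metrics are drawn to straddle every filter threshold (values
    below, at, and above each cutoff) and genotypes mix hom-alt with het.
    With ``hotspot`` ({gene: residues}), a fraction of records is forced to
    be missense at those residues.  The truth table carries, per record and
    strain, the expected filter outcome and the expected class/residue from
    a full-translation oracle.
    """
    if not genes:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    strains = [f"strain{n:03d}" for n in range(n_strains)]
    chrom = next(iter(genome))
    seq = genome[chrom]
    gene_list = list(genes.values())

    depth_pool = [1.0, 2.0, 8.0, 30.0]
    mq_pool = [30.0, 35.0, 40.0, 55.0, 60.0]
    gq_pool = [10.0, 25.0, 30.0, 60.0, 99.0]
    gd_pool = [2.0, 4.0, 5.0, 12.0, 30.0]

    hotspot_targets: List[Tuple[CDSAnnotation, int]] = []
    if hotspot:
        for gene_id, residues in hotspot.items():
            for q in residues:
                hotspot_targets.append((genes[gene_id], int(q)))

    used_positions: Set[int] = set()
    rows = []
    records = []
    attempts = 0
    while len(records) < n_snps and attempts < 50 * max(n_snps, 1):
        attempts += 1
        force_hotspot = bool(hotspot_targets) and rng.random() < hotspot_fraction
        if force_hotspot:
            cds, residue = hotspot_targets[rng.integers(len(hotspot_targets))]
            codon_positions = cds.cds_positions()[(residue - 1) * 3 : residue * 3]
            pos = int(codon_positions[rng.integers(3)])
        else:
            pos = int(rng.integers(1, len(seq) + 1))
        if pos in used_positions:
            continue
        ref = seq[pos - 1]
        alts = [b for b in _BASES if b != ref]
        rng.shuffle(alts)
        chosen = None
        for alt in alts:
            if not force_hotspot:
                chosen = alt
                break
            kind, res = _mutation_truth(genome, cds, pos, alt)
            if kind == "nsSNP" and res == residue:
                chosen = alt
                break
        if chosen is None:
            continue
        used_positions.add(pos)
        strain = strains[rng.integers(n_strains)]
        depth = float(depth_pool[rng.integers(len(depth_pool))])
        mq = float(mq_pool[rng.integers(len(mq_pool))])
        gq = float(gq_pool[rng.integers(len(gq_pool))])
        gd = float(gd_pool[rng.integers(len(gd_pool))])
        homozygous = bool(rng.random() < 0.85) if not force_hotspot else True
        if force_hotspot:  # hotspot records must survive the quality filter
            depth, mq, gq, gd = 30.0, 60.0, 99.0, 30.0
        passes = (
            homozygous
            and depth >= 2.0
            and mq >= 40.0
            and gq >= 30.0
            and gd >= 5.0
        )
        # Expected class against every gene whose CDS contains the position.
        kind, residue_idx, gene_hit = "intergenic", None, ""
        for candidate in gene_list:
            if candidate.genomic_to_cds(pos) is not None:
                kind, residue_idx = _mutation_truth(genome, candidate, pos, chosen)
                gene_hit = candidate.gene_id
                break
        records.append((pos, ref, chosen, strain, depth, mq, gq, gd, homozygous))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": chosen,
                "strain": strain,
                "expected_pass": passes,
                "expected_class": kind,
                "expected_residue": residue_idx if residue_idx is not None else -1,
                "gene": gene_hit,
            }
        )

    records.sort(key=lambda r: r[0])
    order = np.argsort([row["pos"] for row in rows], kind="stable")
    rows = [rows[i] for i in order]

    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={len(seq)}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Genotype depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(strains),
    ]
    body = []
    for pos, ref, alt, strain, depth, mq, gq, gd, homozygous in records:
        gt = "1/1" if homozygous else "0/1"
        fields = []
        for s in strains:
            if s == strain:
                fields.append(f"{gt}:{int(gq)}:{int(gd)}")
            else:
                fields.append("0/0:99:30")
        body.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\t"
            f"DP={int(depth)};MQ={mq:g}\tGT:GQ:DP\t" + "\t".join(fields)
        )
    Path(out_vcf).write_text("\n".join(header + body) + "\n")
    return pd.DataFrame(rows)
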