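"""SNP quality filtering, coding-effect classification and mutation profiles.

Variants come in as per-strain single-nucleotide records (typically read
from a multi-sample VCF).  Low-quality calls are removed with the standard
GATK-style thresholds, surviving homozygous SNPs are mapped into coding
sequences strand-aware and classified as synonymous (sSNP), nonsynonymous
(nsSNP) or intergenic, and nsSNP residue positions are aggregated into
per-protein mutation profiles for the 3D clustering statistics.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "SNPRecord",
    "CDSAnnotation",
    "SNPClassification",
    "MutationProfile",
    "FILTER_THRESHOLDS",
    "filter_snps",
    "classify_snp",
    "relative_mutation_load",
    "build_mutation_profiles",
    "read_vcf",
]

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Records *below* any of these are discarded (strict-inequality removal, so a
# record exactly at a threshold is kept).
FILTER_THRESHOLDS = {
    "depth": 2.0,
    "mapping_quality": 40.0,
    "genotype_quality": 30.0,
    "genotype_depth": 5.0,
}


@dataclass(frozen=True)
class SNPRecord:
    strain: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: Optional[float] = None
    mapping_quality: Optional[float] = None
    genotype_quality: Optional[float] = None
    genotype_depth: Optional[float] = None
    homozygous: bool = True

    def __post_init__(self):
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"SNPs must be single nucleotides, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")


def filter_snps(
    records: Iterable[SNPRecord], with_counts: bool = False
):
    """Quality filter: keep homozygous records with depth ≥ 2.0, mapping
    quality ≥ 40, genotype quality ≥ 30 and genotype depth ≥ 5.

    Records missing any metric cannot be scored and are dropped, counted
    separately as ``unscorable``.
    """
    kept: List[SNPRecord] = []
    counts = {"kept": 0, "filtered": 0, "heterozygous": 0, "unscorable": 0}
    for rec in records:
        metrics = (
            rec.depth,
            rec.mapping_quality,
            rec.genotype_quality,
            rec.genotype_depth,
        )
        if any(m is None for m in metrics):
            counts["unscorable"] += 1
            continue
        if not rec.homozygous:
            counts["heterozygous"] += 1
            continue
        if (
            rec.depth < FILTER_THRESHOLDS["depth"]
            or rec.mapping_quality < FILTER_THRESHOLDS["mapping_quality"]
            or rec.genotype_quality < FILTER_THRESHOLDS["genotype_quality"]
            or rec.genotype_depth < FILTER_THRESHOLDS["genotype_depth"]
        ):
            counts["filtered"] += 1
            continue
        kept.append(rec)
        counts["kept"] += 1
    if with_counts:
        return kept, counts
    return kept


@dataclass(frozen=True)
class CDSAnnotation:
    """A coding gene: ordered exon intervals (1-based, inclusive) and strand.

    The CDS includes the stop codon, so the encoded protein length is
    CDS length / 3 − 1.
    """

    gene_id: str
    chrom: str
    exons: Tuple[Tuple[int, int], ...]
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon {start}-{end} of {self.gene_id} is inverted")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.gene_id} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3 - 1

    def cds_positions(self) -> List[int]:
        """Genomic positions of the CDS in translation order (5'→3' of the
        coding strand)."""
        positions = [p for start, end in self.exons for p in range(start, end + 1)]
        return positions[::-1] if self.strand == "-" else positions

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """1-based CDS coordinate of a genomic position, None if outside."""
        try:
            return self.cds_positions().index(pos) + 1
        except ValueError:
            return None


@dataclass(frozen=True)
class SNPClassification:
    kind: str  # "sSNP" | "nsSNP" | "intergenic"
    residue: Optional[int] = None  # 1-based codon index in the protein
    ref_residue: Optional[str] = None
    alt_residue: Optional[str] = None


def _coding_base(base: str, strand: str) -> str:
    return base.translate(_COMPLEMENT) if strand == "-" else base


def classify_snp(
    record: SNPRecord, cds: CDSAnnotation, genome: Mapping[str, str]
) -> SNPClassification:
    """Classify a SNP against one gene's CDS.

    The genomic reference base must match the genome sequence (an assembly
    mismatch is an error, not a call).  Positions outside the CDS are
    intergenic; inside, the affected codon is rebuilt strand-aware and
    translated with the standard nuclear code.  A change in the stop codon
    that loses the stop is nonsynonymous.
    """
    seq = genome[record.chrom]
    genome_base = seq[record.pos - 1].upper()
    if genome_base != record.ref:
        raise ValueError(
            f"reference mismatch at {record.chrom}:{record.pos}: VCF says "
            f"{record.ref}, genome has {genome_base}"
        )
    cds_pos = cds.genomic_to_cds(record.pos)
    if cds_pos is None:
        return SNPClassification("intergenic")
    codon_index = (cds_pos - 1) // 3 + 1
    offset = (cds_pos - 1) % 3
    positions = cds.cds_positions()
    codon_genomic = positions[(codon_index - 1) * 3 : codon_index * 3]
    ref_codon = "".join(
        _coding_base(seq[p - 1].upper(), cds.strand) for p in codon_genomic
    )
    alt_codon = list(ref_codon)
    alt_codon[offset] = _coding_base(record.alt, cds.strand)
    alt_codon = "".join(alt_codon)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    kind = "sSNP" if ref_aa == alt_aa else "nsSNP"
    return SNPClassification(kind, codon_index, ref_aa, alt_aa)


def relative_mutation_load(
    counts: Mapping[str, Tuple[int, int]], protein_lengths: Mapping[str, int]
) -> Dict[str, Tuple[float, float]]:
    """Per-gene relative sSNP and nsSNP load: count / protein length."""
    out: Dict[str, Tuple[float, float]] = {}
    for gene, (s_count, ns_count) in counts.items():
        length = protein_lengths.get(gene)
        if not length:
            logger.warning("gene %r has no protein length; skipped", gene)
            continue
        out[gene] = (s_count / length, ns_count / length)
    return out


@dataclass
class MutationProfile:
    """Per-protein missense burden: residue index → number of mutated samples."""

    protein_id: str
    counts: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        for residue, n in self.counts.items():
            if n < 1:
                raise ValueError(f"residue {residue}: sample count must be ≥ 1")

    @property
    def residues(self) -> List[int]:
        return sorted(self.counts)


def build_mutation_profiles(
    records: Iterable[SNPRecord],
    annotations: Mapping[str, CDSAnnotation],
    genome: Mapping[str, str],
) -> Dict[str, MutationProfile]:
    """Filtered records → per-protein nsSNP profiles.

    A residue's count is the number of distinct strains carrying a missense
    mutation at it (several SNPs of one strain in one codon count once).
    """
    hits: Dict[str, Dict[int, set]] = defaultdict(lambda: defaultdict(set))
    for rec in records:
        for gene_id, cds in annotations.items():
            if cds.chrom != rec.chrom:
                continue
            result = classify_snp(rec, cds, genome)
            if result.kind == "nsSNP" and result.residue is not None:
                hits[gene_id][result.residue].add(rec.strain)
    return {
        gene: MutationProfile(gene, {q: len(strains) for q, strains in res.items()})
        for gene, res in hits.items()
    }


def read_vcf(path) -> List[SNPRecord]:
    """Read per-strain SNP records from a (multi-sample) VCF.

    Site metrics DP and MQ come from INFO; GQ and per-sample depth from the
    FORMAT fields.  Samples with a reference genotype are skipped; other
    genotypes produce one record each, flagged heterozygous when applicable.
    Non-SNP variants are ignored.
    """
    from cyvcf2 import VCF

    records: List[SNPRecord] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for variant in vcf:
        if not variant.is_snp or len(variant.ALT) != 1:
            continue
        depth = variant.INFO.get("DP")
        mq = variant.INFO.get("MQ")
        gt_types = variant.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        fmt_gq = variant.format("GQ")
        fmt_dp = variant.format("DP")
        for i, sample in enumerate(samples):
            if gt_types[i] in (0, 2):
                continue
            gq = float(fmt_gq[i][0]) if fmt_gq is not None and fmt_gq[i][0] >= 0 else None
            gd = float(fmt_dp[i][0]) if fmt_dp is not None and fmt_dp[i][0] >= 0 else None
            records.append(
                SNPRecord(
                    strain=sample,
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=variant.ALT[0],
                    depth=float(depth) if depth is not None else None,
                    mapping_quality=float(mq) if mq is not None else None,
                    genotype_quality=gq,
                    genotype_depth=gd,
                    homozygous=gt_types[i] == 3,
                )
            )
    return records
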