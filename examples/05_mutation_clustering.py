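"""SNP filtering/classification and 3D mutation clustering (CLUMPS, hotspots)."""

import tempfile
from pathlib import Path

from pangem import (
    WAPParams,
    build_mutation_profiles,
    clumps_pvalue,
    filter_snps,
    hotspot_clusters,
    hotspot_pairs,
    read_vcf,
)
from pangem import fixtures as fx

# Synthetic chromosome with coding genes on both strands, a multi-sample VCF
# enriched for missense mutations at four spatially clustered residues.
genome, genes = fx.make_synthetic_genes(seed=3, n_genes=2, protein_length=60)
gene_id = "G001"
structure = fx.make_chain_structure(60, "compact", protein_id=gene_id)

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "strains.vcf"
    fx.make_synthetic_vcf(
        genes, genome, 60, vcf, seed=1,
        hotspot={gene_id: [5, 25, 7, 27]}, hotspot_fraction=0.8,
    )
    records, counts = filter_snps(read_vcf(vcf), with_counts=True)
    print("quality filter:", counts)
    profiles = build_mutation_profiles(records, genes, genome)

profile = profiles[gene_id]
print(f"{gene_id}: missense burden at residues {profile.residues}")

wap, p = clumps_pvalue(profile, structure, WAPParams(randomizations=10_000, seed=1))
print(f"WAP = {wap:.4f}, CLUMPS p = {p:.4f}")
# the enriched residues sit close together on the compact fold, so the
# observed proximity score beats almost all uniform repositionings.

pairs = hotspot_pairs(profile, structure, seed=1)
for pair in pairs:
    print(f"significant pair {pair.residue_a}-{pair.residue_b}: "
          f"{pair.distance:.1f} Å apart, {pair.separation} residues in "
          f"sequence, p = {pair.p_value:.4f}")
for cluster in hotspot_clusters(pairs, profile, structure, WAPParams(seed=1)):
    print(f"hotspot zone {sorted(cluster.residues)}: p = {cluster.p_value:.4f}")
# pairs must be < 10 Å apart yet ≥ 20 residues apart in sequence; the zones
# are connected components of the significant-pair graph.
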