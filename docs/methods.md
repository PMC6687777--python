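# Methods

This note documents the models, numerical choices and synthetic-data design
behind `pangem`, and what the test suite does and does not establish.

## Constraint-based core

A model is a stoichiometric matrix `S` over metabolites × reactions with
flux bounds (mmol·gDW⁻¹·h⁻¹) and one GPR boolean rule per reaction. FBA and
FVA are linear programs solved with HiGHS (`scipy.optimize.linprog`);
cobrapy is used for SBML I/O and, in the tests, as an independent solver
route, never as the implementation. Tolerances: primal feasibility 1e-9 at
the solver, 1e-6 for all steady-state and bound assertions, 1e-9 relative
on objective comparisons. FVA pins the objective with an equality row and
minimizes/maximizes each reaction in turn; with alternate optima FBA returns
an arbitrary optimal vertex, so no test or result ever asserts a specific
alternate optimum — only objective values and FVA ranges.

*Exchanges* are single-metabolite reactions (`met ↔ ∅`); uptake is negative
flux. Applying a `Medium` opens the listed exchanges at `−rate` and closes
uptake through all others, the usual minimal-medium convention.

*Dead ends* are metabolites for which no pair of **distinct** reactions can
produce and consume them given reversibility. This deliberately includes a
metabolite touching only one reversible reaction: a reaction has one net
flux, so it cannot act as producer and consumer simultaneously; the LP
confirms such metabolites are blocked.

*Mass balance* multiplies stoichiometric coefficients by elemental formula
counts per element and reports imbalances above 1e-6; exchanges are skipped
and reactions touching a formula-less metabolite (e.g. biomass) are flagged
`unverifiable` rather than treated as errors.

## GPR rules

Rules are monotone AND/OR trees over gene ids, parsed from the conventional
infix text with AND binding tighter than OR. The empty rule is true
(spontaneous/pseudo-reactions always survive carving). Pruning restricts a
true rule to a gene set: absent OR-alternatives are dropped and an AND
clause with an absent subunit is dropped whole; the result is logically
equivalent to the original with absent genes fixed false (tested by truth
table against an independent evaluator).

## Enzyme-constrained construction

Per catalyzed reaction, each coupled enzyme is consumed at `−1/kcat`; usage
pseudo-reactions supply enzyme species either up to a concentration bound
`[E_i]` or from a shared pool metabolite at `MW_i` grams per mmol drawn.
Pool capacity defaults to `P_total·f·σ = 0.5 × 0.5 × 0.5 = 0.125 g·gDW⁻¹`
(the conventional GECKO-style parameterization for a budding-yeast-like
cell: ~0.5 g protein/gDW, about half of it metabolic enzymes, average
saturation one half); all three factors are configurable. When several kcat
values exist for an (enzyme, reaction) pair the largest is kept. Reversible
catalyzed reactions are split into irreversible pairs (`<rxn>`/`<rxn>_REV`)
so the coupling coefficient has one sign; isoenzyme alternatives become
copies `<rxn>_No<k>` and a parent map projects copy fluxes back
(`net = Σ forward − Σ reverse`). Subunits without kinetic data carry no
enzyme cost rather than blocking the reaction.

Parsimonious simulation maximizes growth, pins it with an equality row, and
minimizes `Σ MW_i·e_i`; the growth value is preserved exactly by
construction (asserted to 1e-9 relative).

**Flux control.** FCCs use the one-sided 0.1 % perturbation in the
definition: all kcats of one enzyme scaled by 1.001 in place, target
re-optimized, model restored. A zero base flux is reported as *undefined*,
never as zero. The tests compare against finite differences computed by
rebuilding the model from scratch at scaled kcat tables. Note for oracle
design: with a shared pool the optimal growth is `C/Σ(MW_i/kcat_i)`-shaped,
i.e. smooth but curved in each kcat, so a central difference at ±0.1 %
differs from the one-sided definition by O(δ) ≈ 1e-4·FCC; the
central-difference agreement test therefore uses concentration-bounded
toys, where the response is piecewise linear and the two coincide. With
individual bounds the ecFVA comparison fixes growth at the enzyme-model
optimum and additionally caps substrate uptake in the base model at the
enzyme-model's optimal uptake, so both describe the same physiology; on
those conditions the summed flux ranges of the constrained model never
exceed the base model's.

## Pan, strain and core models

Ortholog merging implements the two field rules: an isoenzyme reference
gains the ortholog as one more OR-alternative (`A or B` → `A or B or C`); a
complex subunit duplicates its AND clause with the reference substituted
(`A and B` → `(A and B) or (C and B)`), applied to every occurrence.
Orthologs below the identity threshold (default 0.8) or with unknown
reference genes are skipped with a log message. Carving keeps a reaction
iff its rule evaluates true, prunes surviving rules, and removes orphan
metabolites (a flag keeps them for intersection bookkeeping); collapsed
gene ids are renamed through a translation table before carving. Model
equality for the core is by id — pan-derived models share a namespace by
construction — and the core keeps exactly the element-wise intersection;
a core reaction may retain a variable gene in its rule when isoenzymes
cover for it, which is reported in the variable-gene set rather than
swallowed. Strains whose carved model cannot grow are reported as such,
never patched.

## Phenotype evaluation

Substrate screens replace the varied element source on a base medium,
open the substrate exchange at 10 mmol·gDW⁻¹·h⁻¹ (the conventional
in-silico uptake), and call growth above 1e-4 h⁻¹; both defaults are
configurable, as no principled universal value exists. Essentiality
disables reactions whose rule fails without the gene and calls a gene
essential below 5 % of wild-type growth (configurable). Chemostats fix
uptake lower bounds to measured values and close other uptakes (a
chemostat runs on a defined medium); under nitrogen limitation the biomass
protein coefficient is multiplied by the rescale factor and the freed
coefficient mass is redistributed proportionally over the other consumed
biomass components — the redistribution rule is this package's documented
choice, as is the reference-ratio scaling in the growth-prediction error
(measured rates scaled so the reference condition matches its prediction,
then mean |pred − scaled|/scaled as a percentage). The printed accuracy
denominator uses FP (the standard definition).

## Structures and mutation clustering

Homology models pass quality control iff QMEAN ≥ −4, sequence identity
≥ 0.25, similarity ≥ 0.31 and resolution ≤ 3.4 Å (all inclusive);
experimental structures require exact sequence identity, resolution
≤ 3.4 Å and no internal gaps. A normal-approximation cutoff
(`mean ± z₀.₉·SD`, z₀.₉ ≈ 1.2816) is provided for deriving thresholds from
metric distributions. Domains are assigned only to structures covering the
whole domain interval. Residues are 1-based throughout; PDB numbering
offsets are resolved when reading Cα traces.

SNP handling keeps homozygous records with depth ≥ 2, mapping quality
≥ 40, genotype quality ≥ 30 and genotype depth ≥ 5 (strict-inequality
removal, so records exactly at a threshold survive); records missing a
metric are counted `unscorable`. Classification maps a genomic position
into CDS coordinates strand-aware (reverse complement on −), rebuilds the
affected codon, and translates with the standard nuclear code; a lost stop
is nonsynonymous. The test oracle instead re-translates the entire mutant
CDS and diffs the proteins — a genuinely independent route.

**WAP/CLUMPS.** WAP sums over *unordered distinct* pairs (the index-set
reading that avoids double counting and self-pairs). The null repositions
mutated residues uniformly without replacement over covered residues,
carrying sample counts; the p-value is `#{WAP_null ≥ WAP_obs}/R` with a
1e-12 absolute tie tolerance. `≥` (the standard permutation convention) is
used: with a strict `>` a profile whose permutations all tie the observed
score would be called maximally significant, inverting the test. The null
is enumerated exhaustively when the placement space (combinations for equal
counts, permutations otherwise) is ≤ 1e5, else sampled with a seeded
generator, R = 10,000 by default. p may be exactly 0 under this estimator;
a `(+1)/(R+1)` correction is deliberately not applied so the printed
formula is reproduced. Hotspot pairs require Cα distance strictly < 10 Å
and sequence separation ≥ 20; each pair's p-value compares its distance to
all (or R sampled) same-separation residue pairs of the same protein's
covered structure — same-protein sampling is this package's choice where
the procedure is underspecified. Zones are connected components; member
closeness is harmonic centrality (Σ 1/graph-distance) on the component, and
each zone gets a CLUMPS p-value over its own residues. Distances use
single-chain Cα coordinates; multi-chain contacts are out of scope.

## Synthetic data

The generators produce the *shape* of real inputs, not their statistics:

* `make_toy_gem` — a feasible growth network (glucose/fructose in, biomass
  out) with at least one isoenzyme rule, one complex rule, empty-rule
  exchanges, a planted dead-end metabolite, and elemental formulas chosen
  so everything except the biomass pseudo-reaction balances. Optional
  parallel routes create true flux variability at fixed growth. Default
  uptake 10 mmol·gDW⁻¹·h⁻¹ pins stoichiometric growth at 10 h⁻¹.
* kcat/enzyme tables — log-uniform kcats in 1e2–1e4 h⁻¹ and molecular
  weights uniform in 20–120 g·mmol⁻¹, the broad physiological ranges.
* presence matrices — an all-present reference strain plus independent
  per-gene dropout (default 0.2), optionally nested for monotonicity tests.
* Cα traces — extended (3.8 Å virtual bond), ideal α-helix, or a compact
  boustrophedon grid in which residues ≥ 20 apart in sequence sit < 10 Å
  apart in space.
* genomes/VCFs — coding genes on both strands, some spliced; VCF records
  straddle every filter threshold, mix hom/het genotypes, and carry a
  generator-side truth table computed by full-translation (not by the
  classifier under test). Hotspot enrichment forces missense hits onto
  chosen residues.

Because the toys are small and noise-free, passing tests establish the
*logic* (boolean semantics, LP algebra, estimator calibration), not
performance on real genomes: no codon-usage bias, no sequencing-error
model, no homology-model coordinate error, and network sizes orders of
magnitude below a real GEM. Reported problem sizes — 50-toy FVA ensembles,
400 null simulations at R = 2000, 500 random SNPs — were chosen as the
smallest ensembles at which the binomial/KS noise of the calibration
checks is well inside the asserted bands.

## Known limitations

* Single-objective LPs only; no thermodynamic/loopless constraints.
* Enzyme constraints assume one kcat per (enzyme, reaction, direction);
  no temperature or proteomics calibration.
* Hotspot null sampling is within-protein; cross-protein pooling is not
  implemented.
* Core-model growth is reported, not repaired: an intersection that cannot
  synthesize biomass stays that way.
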