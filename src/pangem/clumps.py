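"""3D clustering of missense mutations: WAP score, CLUMPS permutation test,
hotspot pair detection and hotspot-zone clustering.

The WAP (weighted average proximity) statistic sums, over unordered pairs of
mutated residues, a Gaussian kernel of their Cα distance weighted by
Hill-normalized sample counts:

    WAP = Σ_{q<r} n_q · n_r · exp(−d²_qr / (2 t²)),
    n_q = N_q^m / (θ^m + N_q^m)

with soft distance threshold t = 6 Å and Hill parameters θ = 2, m = 3 by
default.  The CLUMPS test repositions the mutated residues uniformly without
replacement over the covered structure (keeping their sample counts) and
reports the right-tailed permutation p-value of the observed WAP.

Hotspot analysis finds pairs of mutated residues that are close in space
(Cα distance < 10 Å) yet distant in sequence (≥ 20 residues apart) and
unusually close compared to random same-separation residue pairs; the
significant pairs are assembled into hotspot zones as connected components
of the residue-pair graph.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .snp import MutationProfile
from .structures import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "WAPParams",
    "HotspotPair",
    "HotspotCluster",
    "hill_weight",
    "wap_score",
    "clumps_pvalue",
    "hotspot_pairs",
    "hotspot_clusters",
]

EXHAUSTIVE_LIMIT = 100_000  # enumerate the null exactly below this many placements


@dataclass(frozen=True)
class WAPParams:
    """Parameters of the WAP statistic and its permutation null."""

    t: float = 6.0  # soft distance threshold, Å
    theta: float = 2.0  # Hill half-saturation sample count
    m: float = 3.0  # Hill steepness
    randomizations: int = 10_000
    seed: Optional[int] = None

    def __post_init__(self):
        if self.t <= 0 or self.theta <= 0 or self.m < 1:
            raise ValueError("require t > 0, θ > 0, m ≥ 1")
        if self.randomizations < 1:
            raise ValueError("need at least one randomization")


def hill_weight(n_samples, theta: float = 2.0, m: float = 3.0):
    """Hill-normalized sample count n = N^m / (θ^m + N^m) ∈ [0, 1)."""
    n_samples = np.asarray(n_samples, dtype=float)
    value = n_samples**m / (theta**m + n_samples**m)
    return float(value) if value.ndim == 0 else value


def _covered_profile(
    profile: MutationProfile, structure: StructureModel
) -> Tuple[np.ndarray, np.ndarray]:
    residues = np.array(profile.residues, dtype=int)
    covered = np.array([structure.covers(int(q)) for q in residues])
    if not covered.all():
        logger.warning(
            "%s: %d mutated residue(s) outside structure coverage dropped",
            profile.protein_id,
            int((~covered).sum()),
        )
    residues = residues[covered]
    counts = np.array([profile.counts[int(q)] for q in residues], dtype=float)
    return residues, counts


def _pair_wap(weights: np.ndarray, kernel: np.ndarray) -> float:
    """Σ_{q<r} w_q w_r K_qr for one placement."""
    outer = np.outer(weights, weights) * kernel
    return float(np.triu(outer, k=1).sum())


def wap_score(
    profile: MutationProfile, structure: StructureModel, params: WAPParams = WAPParams()
) -> float:
    """Observed WAP of a mutation profile on a structure.

    Mutated residues outside the coverage interval are dropped with a
    warning; fewer than two covered residues is degenerate and scores 0.
    """
    residues, counts = _covered_profile(profile, structure)
    if len(residues) < 2:
        logger.warning("%s: fewer than two covered mutated residues; WAP = 0 (degenerate)",
                       profile.protein_id)
        return 0.0
    coords = structure.residue_coords(residues)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    kernel = np.exp(-d2 / (2.0 * params.t**2))
    weights = hill_weight(counts, params.theta, params.m)
    return _pair_wap(weights, kernel)


def _placement_space(n_positions: int, k: int, distinct_weights: bool) -> float:
    if distinct_weights:
        return math.perm(n_positions, k)
    return math.comb(n_positions, k)


def clumps_pvalue(
    profile: MutationProfile,
    structure: StructureModel,
    params: WAPParams = WAPParams(),
    exhaustive: "bool | str" = "auto",
) -> Tuple[float, float]:
    """Right-tailed CLUMPS permutation p-value of the observed WAP.

    The null repositions the mutated residues uniformly without replacement
    over the covered residues, carrying their sample counts unchanged;
    p = #{WAP_null ≥ WAP_obs} / #placements.  The null is enumerated
    exhaustively when the placement space is small (≤ 1e5 by default, or
    when ``exhaustive=True``), otherwise sampled ``params.randomizations``
    times from ``params.seed``.
    """
    residues, counts = _covered_profile(profile, structure)
    k = len(residues)
    if k < 2:
        raise ValueError(
            f"{profile.protein_id}: need ≥ 2 covered mutated residues, have {k}"
        )
    positions = np.array(list(structure.covered_residues), dtype=int)
    n_pos = len(positions)
    coords = structure.residue_coords(positions)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    kernel = np.exp(-d2 / (2.0 * params.t**2))
    weights = hill_weight(counts, params.theta, params.m)
    obs_idx = np.searchsorted(positions, residues)
    wap_obs = _pair_wap(weights, kernel[np.ix_(obs_idx, obs_idx)])

    distinct = len(set(counts)) > 1
    space = _placement_space(n_pos, k, distinct)
    use_exhaustive = exhaustive is True or (
        exhaustive == "auto" and space <= EXHAUSTIVE_LIMIT
    )

    pair_idx = list(itertools.combinations(range(k), 2))
    w_pair = np.array([weights[a] * weights[b] for a, b in pair_idx])

    tol = 1e-12  # absorb float noise in ≥ comparisons
    if use_exhaustive:
        placements = (
            itertools.permutations(range(n_pos), k)
            if distinct
            else itertools.combinations(range(n_pos), k)
        )
        total = hits = 0
        for placement in placements:
            wap = sum(
                w_pair[i] * kernel[placement[a], placement[b]]
                for i, (a, b) in enumerate(pair_idx)
            )
            total += 1
            if wap >= wap_obs - tol:
                hits += 1
        return wap_obs, hits / total

    rng = np.random.default_rng(params.seed)
    R = params.randomizations
    # Uniform k-subsets in random order: argsort of iid uniforms per row.
    idx = np.argsort(rng.random((R, n_pos)), axis=1)[:, :k]
    wap_null = np.zeros(R)
    for i, (a, b) in enumerate(pair_idx):
        wap_null += w_pair[i] * kernel[idx[:, a], idx[:, b]]
    p = float(np.count_nonzero(wap_null >= wap_obs - tol)) / R
    return wap_obs, p


# ---------------------------------------------------------------------------
# hotspot pairs and zones
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HotspotPair:
    residue_a: int
    residue_b: int
    distance: float  # Cα distance, Å
    p_value: float

    @property
    def separation(self) -> int:
        return abs(self.residue_b - self.residue_a)


def hotspot_pairs(
    profile: MutationProfile,
    structure: StructureModel,
    d_max: float = 10.0,
    min_separation: int = 20,
    pair_p_threshold: float = 0.05,
    randomizations: Optional[int] = None,
    seed: Optional[int] = None,
) -> List[HotspotPair]:
    """Significant close-in-space, distant-in-sequence mutated residue pairs.

    Candidates are mutated-residue pairs with Cα distance < ``d_max`` and
    sequence separation ≥ ``min_separation``.  Each candidate's p-value is
    the fraction of same-separation-rule residue pairs on the covered
    structure that are closer than it: exhaustive over all such pairs when
    ``randomizations`` is None, otherwise estimated from that many uniformly
    drawn pairs.  Pairs with p < ``pair_p_threshold`` are returned.
    """
    residues, _ = _covered_profile(profile, structure)
    first, last = structure.coverage
    if last - first < min_separation:
        logger.warning(
            "%s: structure covers only %d residues (< min_separation + 1); no pairs",
            profile.protein_id,
            last - first + 1,
        )
        return []
    positions = np.array(list(structure.covered_residues), dtype=int)
    coords = structure.residue_coords(positions)
    candidates = []
    for qa, qb in itertools.combinations(sorted(int(q) for q in residues), 2):
        if abs(qb - qa) < min_separation:
            continue
        d = float(np.linalg.norm(
            structure.residue_coords([qa])[0] - structure.residue_coords([qb])[0]
        ))
        if d < d_max:
            candidates.append((qa, qb, d))
    if not candidates:
        return []

    # Null population: every residue pair on the covered structure obeying
    # the same separation rule.
    ii, jj = np.triu_indices(len(positions), k=1)
    sep_ok = np.abs(positions[jj] - positions[ii]) >= min_separation
    ii, jj = ii[sep_ok], jj[sep_ok]
    null_d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    if randomizations is not None:
        rng = np.random.default_rng(seed)
        null_d = rng.choice(null_d, size=randomizations, replace=True)
    n_total = len(null_d)

    out = []
    for qa, qb, d in candidates:
        p = float(np.count_nonzero(null_d < d)) / n_total
        if p < pair_p_threshold:
            out.append(HotspotPair(qa, qb, d, p))
    return out


@dataclass
class HotspotCluster:
    """A hotspot zone: one connected component of the significant-pair graph."""

    residues: FrozenSet[int]
    pairs: Tuple[HotspotPair, ...]
    closeness: Dict[int, float]  # Σ over other members of 1/graph distance
    p_value: float  # CLUMPS p-value over the zone's residues only


def hotspot_clusters(
    pairs: Sequence[HotspotPair],
    profile: MutationProfile,
    structure: StructureModel,
    params: WAPParams = WAPParams(),
) -> List[HotspotCluster]:
    """Group significant pairs into hotspot zones (graph components).

    Per zone, member closeness is the sum over the other members of the
    reciprocal graph distance (harmonic centrality on the component), and a
    CLUMPS p-value is computed on the zone's residues alone.
    """
    if not pairs:
        return []
    graph = nx.Graph()
    for pair in pairs:
        graph.add_edge(pair.residue_a, pair.residue_b)
    clusters = []
    for component in sorted(nx.connected_components(graph), key=min):
        sub = graph.subgraph(component)
        closeness = nx.harmonic_centrality(sub)
        member_pairs = tuple(
            p for p in pairs if p.residue_a in component and p.residue_b in component
        )
        sub_profile = MutationProfile(
            profile.protein_id,
            {q: profile.counts[q] for q in component if q in profile.counts},
        )
        _, p = clumps_pvalue(sub_profile, structure, params)
        clusters.append(
            HotspotCluster(
                residues=frozenset(component),
                pairs=member_pairs,
                closeness={q: float(c) for q, c in closeness.items()},
                p_value=p,
            )
        )
    return clusters
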