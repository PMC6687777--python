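"""WAP statistic, CLUMPS permutation test and hotspot pair/zone analysis."""

import itertools
import math

import numpy as np
import pytest

from pangem import (
    MutationProfile,
    WAPParams,
    clumps_pvalue,
    hill_weight,
    hotspot_clusters,
    hotspot_pairs,
    wap_score,
)
from pangem import fixtures as fx
from pangem.structures import StructureModel


def structure_from_coords(coords, first=1, protein_id="P1"):
    coords = np.asarray(coords, dtype=float)
    return StructureModel(
        protein_id=protein_id, source="homology",
        coverage=(first, first + len(coords) - 1), coordinates=coords,
        qmean=-1.0, identity=0.9, similarity=0.9, resolution=2.0,
    )


class TestHill:
    def test_half_saturation_at_theta(self):
        assert hill_weight(2, theta=2, m=3) == pytest.approx(0.5)

    def test_zero_count_is_zero(self):
        assert hill_weight(0) == 0.0

    def test_direct_arithmetic(self):
        assert hill_weight(4, theta=2, m=3) == pytest.approx(8 / 9)

    def test_monotone_and_saturating(self):
        values = hill_weight(np.arange(0, 50), theta=2, m=3)
        assert (np.diff(values) > 0).all()
        assert values[-1] < 1.0 and values[-1] > 0.99


class TestWAP:
    def test_single_mutated_residue_is_degenerate_zero(self):
        st = fx.make_chain_structure(10)
        assert wap_score(MutationProfile("P1", {3: 5}), st) == 0.0

    def test_two_residue_hand_value(self):
        # N = 2 each → n = 0.5; d = 6 Å, t = 6 → 0.25·exp(−1/2)
        st = structure_from_coords([[0, 0, 0], [6, 0, 0]])
        wap = wap_score(MutationProfile("P1", {1: 2, 2: 2}), st)
        assert wap == pytest.approx(0.25 * math.exp(-0.5), rel=1e-12)

    def test_expanding_coordinates_strictly_decreases_wap(self):
        st = fx.make_chain_structure(20, "compact")
        profile = MutationProfile("P1", {2: 2, 7: 1, 15: 3})
        bigger = structure_from_coords(st.coordinates * 2.0)
        assert wap_score(profile, bigger) < wap_score(profile, st)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        st = fx.make_chain_structure(30, "compact")
        profile = MutationProfile("P1", {1: 1, 9: 4, 22: 2, 28: 1})
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = structure_from_coords(st.coordinates @ q.T + [10.0, -3.0, 7.0])
        assert wap_score(profile, moved) == pytest.approx(
            wap_score(profile, st), abs=1e-9
        )

    def test_uncovered_residues_dropped(self):
        st = structure_from_coords([[0, 0, 0], [6, 0, 0]], first=10)
        profile = MutationProfile("P1", {10: 2, 11: 2, 99: 7})
        assert wap_score(profile, st) == pytest.approx(0.25 * math.exp(-0.5))


class TestCLUMPS:
    def test_saturated_profile_has_p_one(self):
        st = fx.make_chain_structure(8)
        profile = MutationProfile("P1", {q: 2 for q in range(1, 9)})
        _, p = clumps_pvalue(profile, st, WAPParams(seed=0))
        assert p == 1.0

    def test_exhaustive_null_on_ten_residue_chain(self):
        # Two adjacent mutations on an extended 10-mer: enumerate all
        # C(10,2) = 45 placements by hand and compare.
        st = fx.make_chain_structure(10)
        profile = MutationProfile("P1", {4: 1, 5: 1})
        wap_obs, p = clumps_pvalue(profile, st, exhaustive=True)
        coords = st.coordinates
        w = hill_weight(1) ** 2
        waps = [
            w * math.exp(-np.sum((coords[a] - coords[b]) ** 2) / 72.0)
            for a, b in itertools.combinations(range(10), 2)
        ]
        expected = sum(1 for x in waps if x >= wap_obs - 1e-12) / len(waps)
        assert p == pytest.approx(expected)
        # adjacent pairs are the closest possible: 9 of 45 tie the observed
        assert p == pytest.approx(9 / 45)

    def test_monte_carlo_matches_exhaustive_within_binomial_ci(self):
        st = fx.make_chain_structure(12, "compact")
        profile = MutationProfile("P1", {2: 1, 5: 1, 11: 1})
        _, p_exact = clumps_pvalue(profile, st, exhaustive=True)
        R = 10_000
        _, p_mc = clumps_pvalue(
            profile, st, WAPParams(randomizations=R, seed=7), exhaustive=False
        )
        half_width = 2.576 * math.sqrt(p_exact * (1 - p_exact) / R)
        assert abs(p_mc - p_exact) <= half_width + 1e-9

    def test_distinct_counts_use_weight_aware_null(self):
        st = fx.make_chain_structure(6)
        profile = MutationProfile("P1", {1: 1, 2: 5})
        wap_obs, p = clumps_pvalue(profile, st, exhaustive=True)
        assert 0.0 < p <= 1.0

    def test_seeded_reproducibility(self):
        st = fx.make_chain_structure(40, "compact")
        profile = MutationProfile("P1", {3: 2, 8: 1, 21: 2, 33: 1})
        params = WAPParams(randomizations=500, seed=11)
        assert clumps_pvalue(profile, st, params, exhaustive=False) == \
            clumps_pvalue(profile, st, params, exhaustive=False)

    def test_fewer_than_two_residues_is_an_error(self):
        st = fx.make_chain_structure(10)
        with pytest.raises(ValueError):
            clumps_pvalue(MutationProfile("P1", {2: 3}), st)


class TestHotspots:
    def test_short_sequence_separation_always_excluded(self):
        # Residues 24/31 sit 7 apart: never a candidate pair, even at 0 Å.
        coords = np.zeros((40, 3))
        coords[:, 0] = np.arange(40) * 0.1  # everything within 4 Å
        st = structure_from_coords(coords)
        profile = MutationProfile("P1", {24: 3, 31: 3})
        assert hotspot_pairs(profile, st) == []

    def test_distant_in_sequence_close_in_space_is_candidate(self):
        st = fx.make_chain_structure(60, "compact")
        profile = MutationProfile("P1", {5: 3, 25: 3})
        pairs = hotspot_pairs(profile, st)
        assert len(pairs) == 1
        assert {pairs[0].residue_a, pairs[0].residue_b} == {5, 25}
        assert pairs[0].separation >= 20 and pairs[0].distance < 10.0

    def test_smallest_distance_pair_has_p_zero_exhaustively(self):
        st = fx.make_chain_structure(60, "compact")
        # find the closest same-separation pair in the structure
        best, best_d = None, np.inf
        for qa, qb in itertools.combinations(range(1, 61), 2):
            if qb - qa < 20:
                continue
            d = np.linalg.norm(st.coordinates[qa - 1] - st.coordinates[qb - 1])
            if d < best_d:
                best, best_d = (qa, qb), d
        profile = MutationProfile("P1", {best[0]: 2, best[1]: 2})
        pairs = hotspot_pairs(profile, st)
        assert len(pairs) == 1 and pairs[0].p_value == 0.0

    def test_pair_set_invariant_to_profile_ordering(self):
        st = fx.make_chain_structure(60, "compact")
        counts = {5: 3, 25: 3, 45: 2, 12: 1}
        forward = hotspot_pairs(MutationProfile("P1", counts), st)
        backward = hotspot_pairs(
            MutationProfile("P1", dict(reversed(list(counts.items())))), st
        )
        assert forward == backward

    def test_tiny_structure_warns_and_returns_empty(self):
        st = fx.make_chain_structure(10)
        assert hotspot_pairs(MutationProfile("P1", {1: 2, 9: 2}), st) == []

    def test_clusters_are_connected_components(self):
        st = fx.make_chain_structure(100, "compact")
        pairs = [
            # hand-built significant pairs: a–b–c chained, x–y separate
            _pair(1, 21), _pair(21, 41), _pair(61, 81),
        ]
        profile = MutationProfile("P1", {1: 2, 21: 2, 41: 2, 61: 2, 81: 2})
        clusters = hotspot_clusters(pairs, profile, st, WAPParams(seed=3))
        assert [sorted(c.residues) for c in clusters] == [[1, 21, 41], [61, 81]]
        # brute-force component oracle
        assert _components({(1, 21), (21, 41), (61, 81)}) == [
            {1, 21, 41}, {61, 81}
        ]

    def test_triangle_closeness_is_two_per_node(self):
        st = fx.make_chain_structure(100, "compact")
        pairs = [_pair(1, 25), _pair(25, 50), _pair(1, 50)]
        profile = MutationProfile("P1", {1: 2, 25: 2, 50: 2})
        (cluster,) = hotspot_clusters(pairs, profile, st, WAPParams(seed=3))
        assert all(c == pytest.approx(2.0) for c in cluster.closeness.values())

    def test_singleton_edge_cluster_delegates_to_clumps(self):
        st = fx.make_chain_structure(60, "compact")
        profile = MutationProfile("P1", {5: 3, 25: 3})
        params = WAPParams(seed=9)
        (cluster,) = hotspot_clusters([_pair(5, 25)], profile, st, params)
        _, expected = clumps_pvalue(
            MutationProfile("P1", {5: 3, 25: 3}), st, params
        )
        assert cluster.p_value == pytest.approx(expected)


def _pair(a, b):
    from pangem.clumps import HotspotPair

    return HotspotPair(a, b, 5.0, 0.01)


def _components(edges):
    """Brute-force connected components by repeated closure."""
    nodes = {n for e in edges for n in e}
    comps = []
    while nodes:
        frontier = {nodes.pop()}
        comp = set()
        while frontier:
            n = frontier.pop()
            comp.add(n)
            for a, b in edges:
                if a == n and b not in comp:
                    frontier.add(b)
                if b == n and a not in comp:
                    frontier.add(a)
        nodes -= comp
        comps.append(comp)
    return sorted(comps, key=min)
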