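"""Tests for triplet enumeration, filtering, ranking and network assembly."""

import numpy as np
import pytest

from rmnet.nro_core import TripletScores, score_triplet
from rmnet.triplet_scan import (
    COMPETITIVE,
    COOPERATIVE,
    RegulatoryNetwork,
    ScoredTriplet,
    SignConflictError,
    ThresholdConfig,
    build_network,
    filter_triplets,
    rank_triplets,
    scan_triplets,
    score_arrays,
)


def _srp(rng, n, k=9):
    x = rng.uniform(0, 1, (n, k))
    lo = x.min(axis=1, keepdims=True)
    return (x - lo) / (x.max(axis=1, keepdims=True) - lo)


def trip(m, c, t, L=0.1, D=0.1, I=None, Ld=None):
    L_d = L / (1 - L) if Ld is None else Ld
    return ScoredTriplet(m, c, t, TripletScores(L, D, L * (1 + D) if I is None else I, L_d))


class TestScan:
    @pytest.mark.parametrize("n, expected", [(3, 6), (5, 60), (10, 720)])
    def test_counts_all_ordered_triples(self, rng, n, expected):
        assert len(scan_triplets(_srp(rng, n))) == expected

    def test_planted_triplet_scores_zero(self, planted_srp):
        scored = {(s.m, s.c, s.t): s for s in scan_triplets(planted_srp)}
        s = scored[(0, 1, 2)]
        assert s.scores.L == 0.0 and s.scores.I == 0.0

    def test_matches_scalar_oracle(self, rng):
        # three-nested-loop scoring via the scalar functions
        srp = _srp(rng, 5)
        scored = {(s.m, s.c, s.t): s.scores for s in scan_triplets(srp)}
        n = srp.shape[0]
        for m in range(n):
            for c in range(n):
                for t in range(n):
                    if len({m, c, t}) != 3:
                        continue
                    ref = score_triplet(srp[m], srp[c], srp[t])
                    got = scored[(m, c, t)]
                    assert got.L == pytest.approx(ref.L, rel=1e-12, abs=1e-12)
                    assert got.D == pytest.approx(ref.D, rel=1e-12, abs=1e-12)
                    assert got.I == pytest.approx(ref.I, rel=1e-12, abs=1e-12)
                    assert got.L_d == pytest.approx(ref.L_d, rel=1e-12, abs=1e-12)

    def test_score_arrays_nan_on_repeated_indices(self, rng):
        arrs = score_arrays(_srp(rng, 4))
        assert np.isnan(arrs["L"][0, 0, 1]) and np.isnan(arrs["I"][2, 1, 2])

    def test_constant_row_rejected(self, rng):
        srp = _srp(rng, 4)
        srp[1] = 0.25
        with pytest.raises(ValueError, match="constant"):
            scan_triplets(srp)

    def test_both_regulator_orders_enumerated(self, rng):
        scored = {(s.m, s.c, s.t) for s in scan_triplets(_srp(rng, 3))}
        assert (0, 1, 2) in scored and (1, 0, 2) in scored


class TestFilterRank:
    def test_boundary_semantics(self):
        cfg = ThresholdConfig(ld_max=0.8, d_max=0.8)
        kept = trip(0, 1, 2, Ld=0.8, D=0.79, L=4 / 9)
        dropped_ld = trip(0, 1, 2, Ld=0.81, D=0.5, L=0.45)
        dropped_d = trip(0, 1, 2, Ld=0.5, D=0.8, L=1 / 3)
        assert filter_triplets([kept, dropped_ld, dropped_d], cfg) == [kept]

    def test_rank_ascending_by_integrated_score(self):
        trips = [trip(0, 1, 2, I=0.3), trip(1, 2, 3, I=0.1), trip(2, 3, 0, I=0.2)]
        assert [t.scores.I for t in rank_triplets(trips)] == [0.1, 0.2, 0.3]

    def test_rank_tie_broken_by_lack_of_fit(self):
        a = trip(0, 1, 2, L=0.2, I=0.5)
        b = trip(1, 2, 3, L=0.1, I=0.5)
        assert rank_triplets([a, b]) == [b, a]

    def test_singleton_unchanged(self):
        t = [trip(0, 1, 2)]
        assert rank_triplets(t) == t


class TestBuildNetwork:
    def test_single_triplet(self):
        net = build_network([trip(0, 1, 2)], otu_ids=["A", "B", "T"])
        assert set(net.nodes) == {"A", "B", "T"}
        assert net.edge_set() == {("A", "T", COOPERATIVE), ("B", "T", COMPETITIVE)}

    def test_union_merges_support(self):
        net = build_network(
            [trip(0, 1, 3), trip(2, 1, 3)], otu_ids=["A", "B", "C", "T"]
        )
        assert len(net) == 3  # A->T coop, C->T coop, B-|T comp (merged)
        assert len(net.nodes) == 4
        assert len(net.edges[("B", "T", COMPETITIVE)]) == 2

    def test_star_topology(self):
        # three triplets sharing a target: three cooperators, one competitor
        trips = [trip(0, 3, 4), trip(1, 3, 4), trip(2, 3, 4)]
        net = build_network(trips, otu_ids=list("XYZWT"))
        coop = [e for e in net.edge_set() if e[2] == COOPERATIVE]
        comp = [e for e in net.edge_set() if e[2] == COMPETITIVE]
        assert len(coop) == 3 and comp == [("W", "T", COMPETITIVE)]

    def test_sign_conflict_raises_by_default(self):
        trips = [trip(0, 1, 2, I=0.1), trip(1, 0, 2, I=0.2)]
        with pytest.raises(SignConflictError):
            build_network(trips)

    def test_permissive_keeps_lower_integrated_score(self):
        trips = [trip(0, 1, 2, I=0.1), trip(1, 0, 2, I=0.2)]
        net = build_network(trips, conflict="permissive")
        # triplet with I=0.1 says 0->2 coop and 1->2 comp; both win
        assert net.edge_set() == {(0, 2, COOPERATIVE), (1, 2, COMPETITIVE)}

    def test_top_k_caps_triplets(self):
        trips = [trip(0, 1, 2, I=0.1), trip(3, 4, 5, I=0.2)]
        net = build_network(trips, top_k=1)
        assert len(net) == 2 and len(net.nodes) == 3

    def test_edge_and_node_bounds(self, rng):
        srp = _srp(rng, 6)
        retained = rank_triplets(
            filter_triplets(scan_triplets(srp), ThresholdConfig(3.8, 3.8))
        )
        net = build_network(retained, conflict="permissive")
        assert len(net) <= 2 * len(retained)
        assert len(net.nodes) <= 3 * len(retained)

    def test_no_self_edges(self):
        net = RegulatoryNetwork()
        with pytest.raises(ValueError):
            net.add_edge("A", "A", COOPERATIVE)

    def test_to_networkx(self):
        net = build_network([trip(0, 1, 2)])
        g = net.to_networkx()
        assert g.number_of_edges() == 2
        assert g.edges[0, 2]["sign"] == COOPERATIVE


def test_pipeline_is_deterministic(rng):
    srp = _srp(rng, 5)
    def run():
        retained = rank_triplets(
            filter_triplets(scan_triplets(srp), ThresholdConfig(1.8, 1.8))
        )
        return [(t.m, t.c, t.t) for t in retained]
    assert run() == run()
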