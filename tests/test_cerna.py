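import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cernaforge import (
    CeRNATriad,
    InteractionPair,
    build_cerna_network,
    network_stats,
    screen_coexpressed_pairs,
    screen_negative_pairs,
    sponge_overlap_test,
)

from conftest import make_matrix


def enumeration_upper_tail(x, K, M, N):
    """Oracle: literally enumerate every M-subset of the universe."""
    hits = total = 0
    for draw in itertools.combinations(range(N), M):
        total += 1
        if sum(1 for item in draw if item < K) >= x:
            hits += 1
    return hits / total if total else 1.0


class TestSpongeTest:
    def test_zero_overlap_is_certain(self):
        assert sponge_overlap_test(0, 4, 5, 10) == 1.0

    def test_worked_example_against_enumeration(self):
        # N=10, K=4, M=5, x=4: C(4,4)*C(6,1)/C(10,5) = 6/252
        p = sponge_overlap_test(4, 4, 5, 10)
        assert p == pytest.approx(6 / 252, abs=1e-15)
        assert p == pytest.approx(enumeration_upper_tail(4, 4, 5, 10), abs=1e-12)

    def test_degenerate_full_universe(self):
        assert sponge_overlap_test(6, 6, 6, 6) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            sponge_overlap_test(3, 2, 5, 10)
        with pytest.raises(ValueError):
            sponge_overlap_test(1, 5, 11, 10)

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_enumeration_and_is_monotone(self, data):
        N = data.draw(st.integers(1, 9))
        K = data.draw(st.integers(0, N))
        M = data.draw(st.integers(0, N))
        ps = [sponge_overlap_test(x, K, M, N) for x in range(min(K, M) + 1)]
        for x, p in enumerate(ps):
            assert p == pytest.approx(enumeration_upper_tail(x, K, M, N), abs=1e-12)
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))  # non-increasing in x
        assert ps[0] == 1.0


class TestScreens:
    def test_monotone_decreasing_retained(self):
        lnc = make_matrix([[1.0, 2, 3, 4, 5]], ["L"], ["A"], 5, layer="lncRNA")
        mir = make_matrix([[10.0, 8, 6, 4, 2]], ["m"], ["A"], 5, layer="miRNA")
        (p,) = screen_negative_pairs(lnc, mir)
        assert p.kind == "lnc_mir" and p.statistic == pytest.approx(-1.0)

    def test_scc_boundary_excluded_strictly(self):
        # ranks (1..5) vs (5,4,1,3,2): Spearman exactly -0.7
        lnc = make_matrix([[1.0, 2, 3, 4, 5]], ["L"], ["A"], 5, layer="lncRNA")
        mir = make_matrix([[5.0, 4, 1, 3, 2]], ["m"], ["A"], 5, layer="miRNA")
        assert screen_negative_pairs(lnc, mir) == []
        assert screen_negative_pairs(lnc, mir, scc_cut=-0.699) != []

    def test_monotone_increasing_dropped(self):
        lnc = make_matrix([[1.0, 2, 3, 4, 5]], ["L"], ["A"], 5, layer="lncRNA")
        mir = make_matrix([[2.0, 4, 6, 8, 10]], ["m"], ["A"], 5, layer="miRNA")
        assert screen_negative_pairs(lnc, mir) == []

    def test_mrna_layer_puts_mirna_first(self):
        mrna = make_matrix([[1.0, 2, 3, 4, 5]], ["G"], ["A"], 5)
        mir = make_matrix([[10.0, 8, 6, 4, 2]], ["m"], ["A"], 5, layer="miRNA")
        (p,) = screen_negative_pairs(mrna, mir)
        assert (p.node_a, p.node_b, p.kind) == ("m", "G", "mir_mrna")

    def test_pcc_scaled_pair_retained(self):
        x = np.exp2([1.0, 2, 3, 4, 5]) - 1
        lnc = make_matrix([x], ["L"], ["A"], 5, layer="lncRNA")
        mrna = make_matrix([3 * (np.exp2([1.0, 2, 3, 4, 5])) - 1], ["G"], ["A"], 5)
        (p,) = screen_coexpressed_pairs(lnc, mrna)
        assert p.statistic == pytest.approx(1.0)

    def test_pcc_boundary_excluded_strictly(self):
        # log2(FPKM+1) vectors (1..5) vs (2,1,3,4,5): Pearson exactly 0.9
        lnc = make_matrix([np.exp2([1.0, 2, 3, 4, 5]) - 1], ["L"], ["A"], 5, layer="lncRNA")
        mrna = make_matrix([np.exp2([2.0, 1, 3, 4, 5]) - 1], ["G"], ["A"], 5)
        assert screen_coexpressed_pairs(lnc, mrna) == []
        assert screen_coexpressed_pairs(lnc, mrna, pcc_cut=0.899) != []

    def test_anticorrelated_pair_dropped(self):
        lnc = make_matrix([np.exp2([1.0, 2, 3, 4, 5]) - 1], ["L"], ["A"], 5, layer="lncRNA")
        mrna = make_matrix([np.exp2([5.0, 4, 3, 2, 1]) - 1], ["G"], ["A"], 5)
        assert screen_coexpressed_pairs(lnc, mrna) == []


def toy_inputs():
    """One clean triad: lnc-G coexpressed, m1/m2 negative with both, targeting both."""
    neg = [
        InteractionPair("L", "m1", "lnc_mir", -0.95),
        InteractionPair("L", "m2", "lnc_mir", -0.9),
        InteractionPair("m1", "G", "mir_mrna", -0.92),
        InteractionPair("m2", "G", "mir_mrna", -0.88),
    ]
    coexp = [InteractionPair("L", "G", "lnc_mrna", 0.97)]
    sponge = {"m1": {"L", "G"}, "m2": {"L", "G"}}
    universe = [f"m{i}" for i in range(1, 21)]
    return neg, coexp, sponge, universe


class TestNetwork:
    def test_no_coexpressed_pairs_means_empty_network(self):
        neg, _, sponge, uni = toy_inputs()
        net = build_cerna_network(neg, [], sponge, universe=uni)
        assert net.triads == [] and net.edges == []

    def test_single_planted_triad_recovered(self):
        neg, coexp, sponge, uni = toy_inputs()
        net = build_cerna_network(neg, coexp, sponge, universe=uni)
        (t,) = net.triads
        assert (t.lncrna_id, t.mrna_id) == ("L", "G")
        assert t.shared_mirnas == {"m1", "m2"}
        assert (t.x, t.K, t.M, t.N) == (2, 2, 2, 20)
        assert t.p_hyper == pytest.approx(enumeration_upper_tail(2, 2, 2, 20), abs=1e-12)

    def test_alpha_zero_empty(self):
        neg, coexp, sponge, uni = toy_inputs()
        assert build_cerna_network(neg, coexp, sponge, alpha=0.0, universe=uni).triads == []

    def test_sponge_needs_both_target_and_correlation_evidence(self):
        neg, coexp, sponge, uni = toy_inputs()
        # m2 targets both but loses its correlation evidence with L
        neg2 = [e for e in neg if not (e.node_a == "L" and e.node_b == "m2")]
        # alpha relaxed: with one shared sponge the overlap is no longer
        # significant at 0.05 (p = 0.1), which is itself part of the point
        (t,) = build_cerna_network(neg2, coexp, sponge, alpha=0.5, universe=uni).triads
        assert t.shared_mirnas == {"m1"}
        assert t.p_hyper == pytest.approx(enumeration_upper_tail(1, 1, 2, 20), abs=1e-12)
        # m2 anti-correlates but no longer targets L
        sponge2 = {"m1": {"L", "G"}, "m2": {"G"}}
        (t,) = build_cerna_network(neg, coexp, sponge2, alpha=0.5, universe=uni).triads
        assert t.shared_mirnas == {"m1"}

    def test_threshold_monotonicity(self, sim_bundle, default_config):
        lnc, mir, mrna = sim_bundle["lnc"], sim_bundle["mir"], sim_bundle["mrna"]
        sponge = sim_bundle["sponge_sets"]
        uni = mir.feature_ids

        def run(scc, pcc, alpha):
            neg = screen_negative_pairs(lnc, mir, scc) + screen_negative_pairs(mrna, mir, scc)
            coexp = screen_coexpressed_pairs(lnc, mrna, pcc)
            net = build_cerna_network(neg, coexp, sponge, alpha=alpha, universe=uni)
            return {(t.lncrna_id, t.mrna_id) for t in net.triads}

        base = run(-0.7, 0.9, 0.05)
        assert run(-0.8, 0.9, 0.05) <= base
        assert run(-0.7, 0.95, 0.05) <= base
        assert run(-0.7, 0.9, 0.01) <= base

    def test_stats_shapes(self):
        neg, coexp, sponge, uni = toy_inputs()
        net = build_cerna_network(neg, coexp, sponge, universe=uni)
        stats = network_stats(net)
        assert stats == {
            "n_lncrna": 1,
            "n_mirna": 2,
            "n_mrna": 1,
            "n_triads": 1,
            "n_lnc_mir_edges": 2,
            "n_mir_mrna_edges": 2,
        }
        # invariant to edge-list input order
        net2 = build_cerna_network(list(reversed(neg)), coexp, sponge, universe=uni)
        assert network_stats(net2) == stats

    def test_empty_network_stats(self):
        from cernaforge import CeRNANetwork

        assert all(v == 0 for v in network_stats(CeRNANetwork([], [])).values())

    def test_triad_invariants_enforced(self):
        with pytest.raises(ValueError):
            CeRNATriad("L", "G", frozenset({"m1"}), 2, 2, 2, 10, 0.01)
        with pytest.raises(ValueError):
            CeRNATriad("L", "G", frozenset({"m1", "m2"}), 2, 1, 2, 10, 0.01)
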