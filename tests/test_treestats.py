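"""Bootstrap, transfer-bootstrap support, enrichment and depth statistics."""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

import strlineage as sl
from strlineage.errors import ConfigError
from strlineage.treestats import internal_node_ids, tree_bipartitions


def nw(text: str) -> dendropy.Tree:
    return sl.read_newick(text)


# ------------------------------------------------------------- bipartitions

class TestBipartition:
    def test_canonicalization_picks_lighter_side_and_is_idempotent(self):
        leaves = frozenset("ABCDE")
        b = sl.Bipartition.canonical({"A", "B", "C"}, leaves)
        assert b.side == frozenset({"D", "E"})
        b2 = sl.Bipartition.canonical(b.side, leaves)
        assert b2 == b

    def test_tied_sizes_break_lexicographically(self):
        leaves = frozenset("ABCD")
        b = sl.Bipartition.canonical({"C", "D"}, leaves)
        assert b.side == frozenset({"A", "B"})


class TestTransferIndex:
    def test_zero_when_branch_present(self):
        ref = nw("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        b = sl.Bipartition.canonical({"A", "B"}, frozenset("ABCDE"))
        assert sl.transfer_index(b, ref) == 0

    def test_matches_exhaustive_dendropy_oracle(self):
        # every reference split against every 5-leaf replicate topology shape
        ref = nw("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        reps = [
            nw("((A:1,C:1):1,((B:1,D:1):1,E:1):1);"),
            nw("((A:1,E:1):1,((B:1,C:1):1,D:1):1);"),
            nw("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);"),
        ]
        for rep in reps:
            rep_splits = []
            tns = dendropy.TaxonNamespace()
            rcopy = dendropy.Tree.get(
                data=sl.write_newick(rep), schema="newick",
                taxon_namespace=tns, preserve_underscores=True,
            )
            rcopy.encode_bipartitions()
            all_labels = frozenset(t.label for t in tns)
            for edge in rcopy.preorder_edge_iter():
                if edge.head_node.parent_node is None:
                    continue
                side = frozenset(
                    l.taxon.label for l in edge.head_node.leaf_iter()
                )
                if side and side != all_labels:
                    rep_splits.append(side)
            for _, b in tree_bipartitions(ref):
                n = len(b.leaves)
                oracle = min(
                    min(len(b.side ^ s), n - len(b.side ^ s)) for s in rep_splits
                )
                oracle = min(oracle, len(b.side))
                assert sl.transfer_index(b, rep) == oracle

    def test_cherry_index_bounded_by_one(self):
        ref = nw("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        rep = nw("((A:1,C:1):1,((B:1,D:1):1,E:1):1);")
        b = sl.Bipartition.canonical({"A", "B"}, frozenset("ABCDE"))
        assert sl.transfer_index(b, rep) in (0, 1)  # delta <= p - 1 with p = 2

    def test_leaf_set_mismatch_rejected(self):
        ref = nw("((A:1,B:1):1,(C:1,D:1):1);")
        b = sl.Bipartition.canonical({"A", "B"}, frozenset("ABCD"))
        with pytest.raises(ConfigError):
            sl.transfer_index(b, nw("((A:1,B:1):1,(C:1,X:1):1);"))


# ----------------------------------------------------------------- bootstrap

class TestBootstrap:
    def test_single_locus_panel_never_drops(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            idx = sl.resample_locus_indices(1, rng)
            assert list(idx) == [0]

    def test_distinct_locus_loss_near_analytic_limit(self):
        # mean fraction of loci absent per replicate -> (1 - 1/L)^L
        L, B = 100, 300
        fractions = []
        for rep in range(B):
            rng = np.random.default_rng([0, rep])
            idx = sl.resample_locus_indices(L, rng)
            fractions.append(1 - len(set(idx.tolist())) / L)
        assert abs(np.mean(fractions) - (1 - 1 / L) ** L) < 0.01

    def test_replicates_deterministic_given_seed(self, standard_analysis):
        m = standard_analysis.matrix.iloc[:12]
        group = list(m.index[:2])
        a = sl.bootstrap_trees(m, group, standard_analysis.panel, B=5, seed=42)
        b = sl.bootstrap_trees(m, group, standard_analysis.panel, B=5, seed=42)
        assert [sl.write_newick(t) for t in a.trees] == [
            sl.write_newick(t) for t in b.trees
        ]
        assert a.dropped_locus_fraction == b.dropped_locus_fraction


class TestTBE:
    def test_branch_in_every_replicate_gets_full_support(self):
        ref = nw("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        supports = sl.tbe_support(ref, [nw(sl.write_newick(ref)) for _ in range(4)])
        assert supports and all(v == 1.0 for v in supports.values())

    def test_half_present_cherry_scores_half(self):
        ref = nw("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        match = nw("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        swap = nw("((A:1,C:1):1,((B:1,D:1):1,E:1):1);")
        supports = sl.tbe_support(ref, [match, swap])
        ids = internal_node_ids(ref)
        ab_node = next(
            n for n, b in tree_bipartitions(ref) if b.side == frozenset({"A", "B"})
        )
        assert supports[ids[id(ab_node)]] == pytest.approx(0.5)

    def test_matches_brute_force_on_bootstrap_sample(self, standard_analysis):
        m = standard_analysis.matrix.iloc[:8]
        group = list(m.index[:2])
        panel = standard_analysis.panel
        dist = sl.pairwise_distance(m)
        prof = sl.compute_root_profile(m, group, panel)
        ref = sl.build_tree(dist, prof, m, panel)
        boot = sl.bootstrap_trees(m, group, panel, B=20, seed=7)
        supports = sl.tbe_support(ref, boot.trees)
        ids = internal_node_ids(ref)
        for node, b in tree_bipartitions(ref):
            p = b.lighter_size
            if p < 2:
                continue
            mean_idx = np.mean([sl.transfer_index(b, t) for t in boot.trees])
            expected = min(max(1 - mean_idx / (p - 1), 0.0), 1.0)
            assert supports[ids[id(node)]] == pytest.approx(expected)


# ---------------------------------------------------------------- enrichment

class TestEnrichment:
    def test_upper_tail_closed_form(self):
        # N=20, K=10, n=5, k=5: only C(10,5) of C(20,5) subsets qualify
        p = sl.hypergeom_upper_tail(5, 5, 10, 20)
        assert p == pytest.approx(252 / 15504, rel=1e-9)

    def test_upper_tail_equals_subset_enumeration(self):
        # exhaustive oracle at N <= 25
        for N, K, n in [(10, 4, 3), (12, 6, 5), (14, 7, 4)]:
            labeled = set(range(K))
            for k in range(0, min(n, K) + 1):
                count = sum(
                    1
                    for subset in itertools.combinations(range(N), n)
                    if len(labeled.intersection(subset)) >= k
                )
                exact = count / math.comb(N, n)
                assert sl.hypergeom_upper_tail(k, n, K, N) == pytest.approx(exact, rel=1e-9)

    def test_zero_hits_and_whole_tree_are_certain(self):
        assert sl.hypergeom_upper_tail(0, 5, 10, 20) == 1.0
        tree = nw("((A:1,B:1):1,(C:1,D:1):1);")
        labels = {"A": "x", "B": "x", "C": "y", "D": "y"}
        results = sl.branch_enrichment(tree, labels, "x")
        whole = [r for r in results if r.n == 4]
        assert all(r.p_value == 1.0 for r in whole)

    def test_unlabeled_leaf_rejected(self):
        tree = nw("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ConfigError):
            sl.branch_enrichment(tree, {"A": "x", "B": "x", "C": "y"}, "x")

    def test_planted_clade_beats_random_relabelings(self, standard_analysis):
        # true-label enrichment must beat the median of 100 permutations
        tree = standard_analysis.tree
        labels = standard_analysis.timepoint_labels
        true_p = min(
            r.p_value for r in sl.branch_enrichment(tree, labels, "relapse")
        )
        rng = np.random.default_rng(3)
        cells = sorted(labels)
        values = [labels[c] for c in cells]
        perm_ps = []
        for _ in range(100):
            shuffled = dict(zip(cells, rng.permutation(values)))
            perm_ps.append(
                min(r.p_value for r in sl.branch_enrichment(tree, shuffled, "relapse"))
            )
        assert true_p < np.median(perm_ps)

    def test_benjamini_hochberg_monotone_and_bounded(self):
        ps = [0.001, 0.02, 0.5, 0.04, 1.0]
        qs = sl.benjamini_hochberg(ps)
        assert all(q >= p for p, q in zip(ps, qs))
        assert all(0 < q <= 1 for q in qs)
        order = np.argsort(ps)
        assert all(np.diff(np.array(qs)[order]) >= -1e-12)


class TestBranchWidth:
    def test_unit_p_gives_minimum_width(self):
        assert sl.branch_width(1.0, w_min=1.5) == 1.5

    def test_smaller_p_is_strictly_wider(self):
        assert sl.branch_width(0.01) > sl.branch_width(0.1)

    def test_pure_function(self):
        assert sl.branch_width(0.037) == sl.branch_width(0.037)

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigError):
            sl.branch_width(0.0)


# ------------------------------------------------------------ depth contrast

class TestDepthComparison:
    def test_exact_p_one_third_for_fully_separated_pairs(self):
        # caterpillar: tie-free depths 1,2,3,4 edges for groups {A,B} vs {C,D}
        tree = nw("(A:1,(B:1,(C:1,(D:1,E:1):1):1):1);")
        res = sl.depth_comparison(tree, ["A", "B"], ["C", "D"], mode="edges")
        brute_u = sum(
            1 for a in res.depths_a for b in res.depths_b if a > b
        ) + 0.5 * sum(1 for a in res.depths_a for b in res.depths_b if a == b)
        assert res.statistic in (brute_u, len(res.depths_a) * len(res.depths_b) - brute_u)
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_depth_multisets_give_p_one(self):
        tree = nw("((A:1,B:1):1,(C:1,D:1):1);")
        res = sl.depth_comparison(tree, ["A", "C"], ["B", "D"], mode="edges")
        assert res.p_value == pytest.approx(1.0)

    def test_overlapping_groups_rejected(self):
        tree = nw("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ConfigError):
            sl.depth_comparison(tree, ["A", "B"], ["B", "C"])

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_diagnosis_wave_sits_shallower_than_relapse(self, seed):
        from conftest import run_standard_analysis

        analysis = run_standard_analysis(seed)
        dx = [c for c, g in analysis.timepoint_labels.items() if g == "diagnosis"]
        rx = [c for c, g in analysis.timepoint_labels.items() if g == "relapse"]
        res = sl.depth_comparison(analysis.tree, dx, rx, mode="length")
        assert np.mean(res.depths_a) < np.mean(res.depths_b)
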