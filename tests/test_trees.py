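"""Gene-tree construction and W-placement topology classification."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from stratascan import sim, trees
from stratascan.trees import (
    SKIPPED,
    UNRESOLVED,
    W_DIVERGENT,
    W_RECENT,
    AlignmentError,
    bootstrap_support,
    classify_topology,
    distance_matrix,
    filter_alignment,
    jc69_distance,
    neighbor_joining,
    root_tree,
    split_key,
    supports_from_tree,
)


def newick(s: str) -> TreeNode:
    # keep underscores literal in leaf labels
    return TreeNode.read(io.StringIO(s), convert_underscores=False)


def splits_of(tree):
    taxa = frozenset(t.name for t in tree.tips())
    return trees._tree_splits(tree, taxa)


class TestFilterAlignment:
    def test_gapless_unchanged(self):
        aln = filter_alignment(["a", "b"], ["ACGT", "ACGA"])
        assert aln.n_cols == 4 and aln.taxa == ["a", "b"]

    def test_column_above_gap_threshold_removed(self):
        # one column gapped in 3 of 7 taxa: 0.43 > 0.40
        seqs = ["A-CT"] * 3 + ["AACT"] * 4
        aln = filter_alignment(list("abcdefg"), seqs)
        assert aln.n_cols == 3

    def test_gappy_taxon_removed_after_columns(self):
        seqs = ["ACGTACGT", "ACGTACGT", "ACGTACGT", "AC----GT"]
        aln = filter_alignment(list("abcd"), seqs)
        assert aln.taxa == ["a", "b", "c"]

    def test_all_columns_removed_errors(self):
        with pytest.raises(AlignmentError):
            filter_alignment(["a", "b"], ["--", "--"])


class TestDistances:
    def test_identical_rows_zero(self):
        aln = filter_alignment(["a", "b"], ["ACGT" * 10] * 2)
        assert jc69_distance(aln.matrix[0], aln.matrix[1]) == 0.0

    def test_value_at_p_01(self):
        row1 = np.frombuffer((b"A" * 100), dtype=np.uint8)
        row2 = np.frombuffer((b"C" * 10 + b"A" * 90), dtype=np.uint8)
        assert jc69_distance(row1, row2) == pytest.approx(0.1073, abs=1e-3)

    def test_saturated_nan(self):
        row1 = np.frombuffer(b"A" * 100, dtype=np.uint8)
        row2 = np.frombuffer(b"C" * 100, dtype=np.uint8)
        assert np.isnan(jc69_distance(row1, row2))

    def test_no_comparable_columns_errors(self):
        row1 = np.frombuffer(b"--AA", dtype=np.uint8)
        row2 = np.frombuffer(b"AA--", dtype=np.uint8)
        with pytest.raises(AlignmentError):
            jc69_distance(row1, row2)


class TestNeighborJoining:
    ADDITIVE = np.array([
        [0, 2, 4, 5],
        [2, 0, 4, 5],
        [4, 4, 0, 3],
        [5, 5, 3, 0],
    ], dtype=float)

    def test_recovers_additive_split(self):
        tree = neighbor_joining(self.ADDITIVE, ["A", "B", "C", "D"])
        assert split_key(frozenset({"A", "B"}), frozenset("ABCD")) in splits_of(tree)

    def test_three_taxa(self):
        dm = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = neighbor_joining(dm, ["A", "B", "C"])
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}

    def test_label_order_invariance(self):
        order = [3, 1, 0, 2]
        labels = ["A", "B", "C", "D"]
        dm2 = self.ADDITIVE[np.ix_(order, order)]
        t1 = neighbor_joining(self.ADDITIVE, labels)
        t2 = neighbor_joining(dm2, [labels[i] for i in order])
        assert splits_of(t1) == splits_of(t2)

    def test_asymmetric_rejected(self):
        bad = self.ADDITIVE.copy()
        bad[0, 1] = 99
        with pytest.raises(ValueError):
            neighbor_joining(bad, ["A", "B", "C", "D"])


class TestBootstrap:
    def _alignment(self):
        groups = sim.simulate_gametologs(None, {"STRATUM1": 1}, seed=3, n_codons=400)
        labels, seqs = groups[0].alignment()
        return filter_alignment(labels, seqs)

    def test_deterministic_under_seed(self):
        aln = self._alignment()
        assert bootstrap_support(aln, 30, seed=5) == bootstrap_support(aln, 30, seed=5)

    def test_supports_in_unit_interval(self):
        support = bootstrap_support(self._alignment(), 30, seed=5)
        assert support and all(0 <= v <= 1 for v in support.values())

    def test_three_taxon_tree_has_no_internal_splits(self):
        aln = filter_alignment(["a", "b", "c"], ["ACGT" * 5, "ACGA" * 5, "AGGA" * 5])
        assert bootstrap_support(aln, 10, seed=1) == {}

    def test_strong_signal_high_support(self):
        # long, clean branches: every internal split should be recovered
        depths = sim.GametologDepths(0.4, 0.2, 0.15, 0.1, 0.3, 0.05, 0.03)
        groups = sim.simulate_gametologs(None, {"STRATUM1": 1}, depths, seed=9,
                                         n_codons=1000)
        labels, seqs = groups[0].alignment()
        aln = filter_alignment(labels, seqs)
        support = bootstrap_support(aln, 50, seed=2)
        # splits backed by long true branches should recur in nearly all
        # replicates (the within-species polytomy has no true resolution,
        # so only signal-bearing splits are asserted)
        grp = groups[0]
        taxa = frozenset(aln.taxa)
        z_label = "female_h2" if grp.w_label == "female_h1" else "female_h1"
        z_clade = frozenset({z_label, "male_h1", "male_h2"})
        for side in (z_clade, z_clade | {"congener2"},
                     z_clade | {"congener2", "congener1"}):
            assert support[trees.split_key(side, taxa)] > 0.9


class TestRooting:
    def test_root_bipartition_is_outgroup_vs_rest(self):
        tree = newick("((A,B),(C,Out));")
        rooted = root_tree(tree, "Out")
        children = {frozenset(t.name for t in c.tips()) or frozenset({c.name})
                    for c in rooted.children}
        assert frozenset({"Out"}) in children
        assert frozenset({"A", "B", "C"}) in children

    def test_missing_outgroup_errors(self):
        from skbio.tree import MissingNodeError
        with pytest.raises(MissingNodeError):
            root_tree(newick("((A,B),C);"), "Out")

    def test_rerooting_idempotent(self):
        tree = newick("((A,B),(C,Out));")
        once = root_tree(tree, "Out")
        twice = root_tree(once, "Out")
        assert splits_of(once) == splits_of(twice)


class TestClassifyTopology:
    def test_divergent_pattern(self):
        t = newick("(outgroup,(female_h2,(congener1,((female_h1,male_h1),male_h2))));")
        call = classify_topology(t, "g")
        assert call.call == W_DIVERGENT
        assert call.w_label == "female_h2"
        assert call.w_outside_congeners is True

    def test_recent_pattern(self):
        t = newick("(outgroup,(congener1,((female_h1,female_h2),(male_h1,male_h2))));")
        call = classify_topology(t, "g")
        assert call.call == W_RECENT

    def test_low_support_unresolved(self):
        t = newick("(outgroup,(female_h2,(congener1,((female_h1,male_h1),male_h2))));")
        taxa = frozenset(x.name for x in t.tips())
        decisive = split_key(frozenset({"female_h1", "male_h1", "male_h2"}), taxa)
        call = classify_topology(t, "g", support={decisive: 0.60})
        assert call.call == UNRESOLVED
        assert call.support == pytest.approx(0.60)

    def test_missing_female_haplotype_skipped(self):
        t = newick("(outgroup,(congener1,(female_h1,(male_h1,male_h2))));")
        assert classify_topology(t, "g").call == SKIPPED

    def test_supports_read_from_newick_labels(self):
        t = newick("(outgroup,(female_h2,(congener1,((female_h1,male_h1),male_h2)90)95)100);")
        support = supports_from_tree(t)
        call = classify_topology(t, "g", support=support)
        assert call.call == W_DIVERGENT

    def test_leaf_order_and_male_swap_invariance(self):
        a = newick("(outgroup,(female_h2,(congener1,((female_h1,male_h1),male_h2))));")
        b = newick("(((male_h1,(male_h2,female_h1)),congener1),female_h2,outgroup);")
        assert classify_topology(a, "g").call == classify_topology(b, "g").call

    def test_recent_without_congeners_trivial_monophyly(self):
        t = newick("(outgroup,((female_h1,female_h2),(male_h1,male_h2)));")
        assert classify_topology(t, "g").call == W_RECENT


class TestEndToEndRecovery:
    def test_stratum_recovery_small(self):
        groups = sim.simulate_gametologs(None, {"STRATUM1": 6, "STRATUM2": 6},
                                         seed=17, n_codons=500)
        outcomes = {"STRATUM1": [], "STRATUM2": []}
        for i, grp in enumerate(groups):
            labels, seqs = grp.alignment()
            aln = filter_alignment(labels, seqs)
            tree = neighbor_joining(distance_matrix(aln), aln.taxa)
            support = bootstrap_support(aln, 100, seed=i)
            call = classify_topology(tree, grp.gene_id, support=support)
            outcomes[grp.true_stratum].append(call)
        s1 = outcomes["STRATUM1"]
        assert sum(c.call == W_DIVERGENT for c in s1) >= 5
        for c in s1:
            if c.call == W_DIVERGENT:
                grp = next(g for g in groups if g.gene_id == c.gene)
                assert c.w_label == grp.w_label
        assert all(c.call != W_DIVERGENT for c in outcomes["STRATUM2"])
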