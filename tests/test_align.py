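"""Pairwise alignment, K2P distances, neighbor joining, bootstrap and
parental-origin classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyhox.align_assign import (
    DistanceMatrix,
    OriginCall,
    assign_paralog_group,
    bootstrap_support,
    build_nj_tree,
    classify_parental_origin,
    estimate_ancestry,
    global_align,
    identity_between,
    inheritance_report,
    kimura2p_distance,
    percent_identity,
)
from polyhox.seqio import SeqRecord
from polyhox.survey import Variant


def var(vid: str, seq: str, species="sp") -> Variant:
    return Variant(vid, species, seq, 1, [f"{vid}.c1"])


class TestGlobalAlign:
    def test_identical_sequences_score_all_matches(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 4 and aln.matches == 4 and aln.aligned_columns == 4

    def test_single_substitution(self):
        aln = global_align("ACGT", "ACGA")
        assert aln.matches == 3 and aln.aligned_columns == 4

    def test_gap_recovery_preserves_inputs(self):
        aln = global_align("ACGTACGT", "ACGACGT")
        assert aln.aligned_a.replace("-", "") == "ACGTACGT"
        assert aln.aligned_b.replace("-", "") == "ACGACGT"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("A", "")


class TestPercentIdentity:
    def test_identity_is_100_for_equal_sequences(self):
        assert percent_identity(global_align("ACGTAC", "ACGTAC")) == 100.00

    def test_three_of_four(self):
        assert percent_identity(global_align("ACGT", "ACGA")) == 75.00

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60),
           st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_symmetry(self, a, b):
        assert identity_between(a, b) == identity_between(b, a)

    def test_all_columns_mode_counts_gaps(self):
        aln = global_align("ACGTACGT", "ACGT")
        assert percent_identity(aln, mode="all_columns") < percent_identity(aln)


class TestKimura2P:
    def test_identical_rows_have_zero_distance(self):
        assert kimura2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_closed_form_for_pure_transitions(self):
        # P = 0.1, Q = 0 over 100 sites: d = -0.5 ln(0.8)
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert kimura2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_saturation_flags_infinite_distance(self):
        a = "A" * 10
        b = "C" * 10  # Q = 1 -> log argument <= 0
        assert math.isinf(kimura2p_distance(a, b))

    def test_gapped_columns_are_ignored(self):
        assert kimura2p_distance("AC-T", "ACGT"[0:2] + "-" + "T") == 0.0

    def test_all_gap_rows_rejected(self):
        with pytest.raises(ValueError):
            kimura2p_distance("---", "---")


def random_additive_tree(rng, n_taxa):
    """Distance matrix of a random binary tree with random branch lengths:
    the additive-matrix oracle for neighbor joining."""
    import itertools

    labels = [f"t{i}" for i in range(n_taxa)]
    d = np.zeros((n_taxa, n_taxa))
    # start from a 3-taxon star, then repeatedly split a random edge and
    # hang the next leaf off the new internal node
    adj = {}

    def add_edge(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    add_edge(labels[0], "x0", rng.uniform(0.1, 1.0))
    add_edge(labels[1], "x0", rng.uniform(0.1, 1.0))
    add_edge(labels[2], "x0", rng.uniform(0.1, 1.0))
    internal = 1
    for leaf in labels[3:]:
        # pick a random existing edge, split it, hang the new leaf
        edges = [(u, v, w) for u in adj for v, w in adj[u] if u < str(v)]
        u, v, w = edges[rng.integers(0, len(edges))]
        adj[u] = [(x, y) for x, y in adj[u] if x != v]
        adj[v] = [(x, y) for x, y in adj[v] if x != u]
        mid = f"x{internal}"
        internal += 1
        cut = rng.uniform(0.05, 0.95) * w
        add_edge(u, mid, cut)
        add_edge(v, mid, w - cut)
        add_edge(leaf, mid, rng.uniform(0.1, 1.0))

    def dist(a, b):
        stack = [(a, 0.0, None)]
        while stack:
            node, acc, prev = stack.pop()
            if node == b:
                return acc
            for nxt, w in adj.get(node, []):
                if nxt != prev:
                    stack.append((nxt, acc + w, node))
        raise RuntimeError("disconnected")

    for i, j in itertools.combinations(range(n_taxa), 2):
        d[i, j] = d[j, i] = dist(labels[i], labels[j])
    return DistanceMatrix(labels, d)


def tree_path_distances(tree):
    tips = sorted(t.name for t in tree.tips())
    dm = tree.tip_tip_distances()
    return {(a, b): dm[a, b] for a in tips for b in tips if a < b}


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"], [[0, 2, 3], [2, 0, 4], [3, 4, 0]])
        tree = build_nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": 0.5, "b": 1.5, "c": 2.5}

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            build_nj_tree(DistanceMatrix(["a", "b"], [[0, 1], [1, 0]]))

    def test_reproduces_random_additive_matrices(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            dm = random_additive_tree(rng, n)
            tree = build_nj_tree(dm)
            got = tree_path_distances(tree)
            labels = dm.labels
            for i, a in enumerate(labels):
                for j in range(i + 1, len(labels)):
                    b = labels[j]
                    key = (a, b) if a < b else (b, a)
                    assert got[key] == pytest.approx(dm.d[i, j], abs=1e-9)

    def test_agrees_with_reference_implementation(self, rng):
        """Independent cross-check against scikit-bio's NJ on additive input."""
        import skbio

        dm = random_additive_tree(rng, 6)
        ours = tree_path_distances(build_nj_tree(dm))
        ref_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.d, dm.labels))
        ref = tree_path_distances(ref_tree)
        for key, val in ours.items():
            assert val == pytest.approx(ref[key], abs=1e-9)

    def test_tie_break_is_deterministic(self):
        dm = DistanceMatrix(["a", "b", "c", "d"], np.ones((4, 4)) - np.eye(4))
        n1 = str(build_nj_tree(dm))
        n2 = str(build_nj_tree(dm))
        assert n1 == n2

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], [[0, 1], [2, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], [[1, 1], [1, 0]])


class TestBootstrap:
    def make_two_clades(self, rng):
        base = "".join(rng.choice(list("ACGT"), 200))
        other = list(base)
        for i in rng.choice(200, 40, replace=False):  # 20% divergence
            other[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[i]]
        other = "".join(other)
        return [SeqRecord("a1", base), SeqRecord("a2", base),
                SeqRecord("b1", other), SeqRecord("b2", other)]

    def test_clean_split_gets_high_support(self, rng):
        recs = self.make_two_clades(rng)
        tree = bootstrap_support(recs, n_reps=200, seed=5)
        supports = [n.support for n in tree.non_tips(include_self=False)
                    if n.support is not None]
        assert supports and min(supports) >= 95

    def test_zero_reps_leaves_supports_empty(self, rng):
        tree = bootstrap_support(self.make_two_clades(rng), n_reps=0, seed=1)
        assert all(n.support is None for n in tree.non_tips(include_self=False))

    def test_same_seed_same_supports(self, rng):
        recs = self.make_two_clades(rng)
        t1 = bootstrap_support(recs, n_reps=50, seed=42)
        t2 = bootstrap_support(recs, n_reps=50, seed=42)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False))
        assert s1 == s2

    def test_too_few_sequences_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support(self.make_two_clades(rng)[:3], n_reps=10, seed=0)


class TestAssignment:
    def panel(self, rng):
        genes = {}
        for g in ("HoxA5a", "HoxB7a", "HoxC9a"):
            genes[g] = "".join(rng.choice(list("ACGT"), 150))
        return [SeqRecord(g, s, description=f"gene={g}") for g, s in genes.items()]

    def test_exact_match_assigns_with_full_identity(self, rng):
        panel = self.panel(rng)
        v = var("q", panel[0].sequence)
        assert assign_paralog_group(v, panel) == ("HoxA5a", 100.0)

    def test_below_floor_returns_unassigned(self, rng):
        panel = self.panel(rng)
        v = var("q", "AC" * 75)
        gene, ident = assign_paralog_group(v, panel, floor=90.0)
        assert gene == "unassigned" and ident < 90

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            assign_paralog_group(var("q", "ACGT" * 10), [])


class TestOriginClassification:
    def setup_method(self):
        self.mA = "AAAAAAAAAA" * 6
        bases = list(self.mA)
        for pos in (9, 19, 39, 49):
            bases[pos] = "C"
        self.pB = "".join(bases)

    def test_exact_match_to_one_parent(self):
        call = classify_parental_origin(
            var("h", self.mA), [var("M-I", self.mA)], [var("P-I", self.pB)]
        )
        assert call.label == "maternal"
        assert call.best_maternal_identity == 100.0
        assert call.best_paternal_identity < 100.0

    def test_match_to_both_parents_is_shared(self):
        call = classify_parental_origin(
            var("h", self.mA), [var("M-I", self.mA)], [var("P-I", self.mA)]
        )
        assert call.label == "shared"

    def test_single_switch_chimera_flagged_as_recombinant(self):
        chimera = self.mA[:30] + self.pB[30:]
        call = classify_parental_origin(
            var("h", chimera), [var("M-I", self.mA)], [var("P-I", self.pB)]
        )
        assert call.label == "recombinant_candidate"

    def test_unrelated_sequence_is_novel(self):
        call = classify_parental_origin(
            var("h", "GTGTGTGTGT" * 6), [var("M-I", self.mA)], [var("P-I", self.pB)]
        )
        assert call.label == "novel"

    def test_both_panels_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_parental_origin(var("h", self.mA), [], [])


class TestInheritance:
    def test_lost_subtype_reported(self):
        m1, m2 = "ACGT" * 20, "TGCA" * 20
        p1 = "ACCT" * 20
        report = inheritance_report(
            [var("h1", m1), var("h2", p1)],
            [var("M-I", m1), var("M-II", m2)],
            [var("P-I", p1)],
        )
        assert report["lost"] == ["M-II"]
        assert sorted(report["retained"]) == ["M-I", "P-I"]
        assert report["novel"] == []

    def test_nothing_lost_when_all_match(self):
        seqs = ["ACGT" * 15, "TTGG" * 15]
        report = inheritance_report(
            [var(f"h{i}", s) for i, s in enumerate(seqs)],
            [var("M-I", seqs[0])],
            [var("P-I", seqs[1])],
        )
        assert report["lost"] == []

    def test_unmatched_hybrid_variant_is_novel(self):
        report = inheritance_report(
            [var("h1", "GGGG" * 15)], [var("M-I", "ACGT" * 15)], []
        )
        assert report["novel"] == ["h1"]


class TestAncestry:
    def call(self, label):
        return OriginCall("v", label, 100.0, 0.0, "m", "p", 100.0)

    def test_balanced_calls_split_evenly(self):
        est = estimate_ancestry([self.call("maternal")] * 2 + [self.call("paternal")] * 2)
        assert est.maternal_fraction == est.paternal_fraction == 0.5

    def test_shared_calls_count_half(self):
        est = estimate_ancestry([self.call("maternal")] * 3 + [self.call("shared")] * 2)
        assert est.maternal_fraction == pytest.approx(4 / 5)
        assert est.n_diagnostic_sites == 5

    def test_pure_maternal_panel(self):
        est = estimate_ancestry([self.call("maternal")] * 4)
        assert (est.maternal_fraction, est.paternal_fraction) == (1.0, 0.0)

    def test_novel_calls_are_excluded(self):
        est = estimate_ancestry([self.call("maternal"), self.call("novel")])
        assert est.maternal_fraction == 1.0 and est.n_diagnostic_sites == 1

    def test_no_usable_calls_rejected(self):
        with pytest.raises(ValueError):
            estimate_ancestry([self.call("novel")])
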