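"""The synthetic allopolyploid clone-library generator."""

import math

import numpy as np
import pytest

from polyhox.seqio import translate
from polyhox.simulate import (
    SimParams,
    simulate_clone_library,
    simulate_hybrid,
    simulate_parents,
    true_cdna,
)
from polyhox.survey import BUILTIN_PRIMER_PAIRS

PAIRS = [BUILTIN_PRIMER_PAIRS["HC9a"]]


def small(**kw) -> SimParams:
    defaults = dict(n_genes=3, seed=7)
    defaults.update(kw)
    return SimParams(**defaults)


class TestParams:
    @pytest.mark.parametrize("field, value", [
        ("parental_divergence", -0.1), ("p_loss", 1.5), ("n_genes", 0),
        ("amplification_bias_concentration", 0.0), ("exon1_length", 10),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            SimParams(**{field: value})

    def test_layout_partitions_the_gene(self):
        p = SimParams()
        assert p.exon1[1] + 1 == p.intron[0]
        assert p.intron[1] + 1 == p.exon2[0]
        assert p.exon2[1] == p.gene_length == 1825


class TestParents:
    def test_zero_divergence_makes_parents_identical(self):
        mat, pat, _ = simulate_parents(small(parental_divergence=0.0))
        for m, p in zip(mat, pat):
            assert m.sequence == p.sequence

    def test_identical_seed_reproduces_panels(self):
        a = simulate_parents(small())
        b = simulate_parents(small())
        assert [r.sequence for r in a[0]] == [r.sequence for r in b[0]]
        assert [r.sequence for r in a[1]] == [r.sequence for r in b[1]]

    def test_divergence_matches_binomial_expectation(self):
        """Mean maternal-vs-paternal mismatch fraction sits within 3 sigma of
        the per-site substitution rate (footprints slightly dilute it)."""
        params = SimParams(n_genes=10, seed=11)
        mat, pat, _ = simulate_parents(params)
        fractions = [
            np.mean([a != b for a, b in zip(m.sequence, p.sequence)])
            for m, p in zip(mat, pat)
        ]
        rate = params.parental_divergence
        sigma = math.sqrt(rate * (1 - rate) / params.gene_length)
        assert abs(np.mean(fractions) - rate) < 3 * sigma

    def test_two_subtypes_per_parent_per_locus(self):
        mat, pat, truth = simulate_parents(small())
        assert len(mat) == len(pat) == 2 * 3
        assert all(truth.copies[r.id]["subtype"] in (1, 2) for r in mat + pat)

    def test_spliced_orf_is_stop_free(self):
        mat, pat, _ = simulate_parents(small(seed=3))
        p = small(seed=3)
        for rec in mat + pat:
            aa = translate(true_cdna(rec, p).sequence)
            assert "*" not in aa[:-1]


class TestHybrid:
    def test_no_events_copies_both_parents_exactly(self):
        p = small(p_loss=0.0, p_recombinant=0.0, p_pseudo=0.0)
        mat, pat, truth = simulate_parents(p)
        hyb, truth = simulate_hybrid(mat, pat, p, truth)
        assert [h.sequence for h in hyb] == [r.sequence for r in mat + pat]
        assert truth.lost_subtypes == []
        assert truth.recombination_events == []
        assert truth.pseudogene_events == []

    def test_all_recombinant_breakpoints_fall_in_the_intron(self):
        p = small(p_recombinant=1.0, p_pseudo=0.0, p_loss=0.0)
        mat, pat, truth = simulate_parents(p)
        _, truth = simulate_hybrid(mat, pat, p, truth)
        i0, i1 = p.intron
        assert len(truth.recombination_events) == len(mat) + len(pat)
        assert all(i0 <= e["true_breakpoint_position"] <= i1
                   for e in truth.recombination_events)

    def test_pseudogenization_changes_length_by_one_or_two(self):
        p = small(p_pseudo=1.0, p_recombinant=0.0, p_loss=0.0)
        mat, pat, truth = simulate_parents(p)
        hyb, truth = simulate_hybrid(mat, pat, p, truth)
        by_id = {r.id: r for r in mat + pat}
        for h in hyb:
            src = by_id[truth.copies[h.id]["source"]]
            assert abs(len(h) - len(src)) in (1, 2)

    def test_copy_count_conservation(self):
        p = small(seed=5)
        mat, pat, truth = simulate_parents(p)
        hyb, truth = simulate_hybrid(mat, pat, p, truth)
        assert len(hyb) == len(mat) + len(pat) - len(truth.lost_subtypes)

    def test_empty_panel_rejected(self):
        p = small()
        with pytest.raises(ValueError):
            simulate_hybrid([], [], p)


class TestCloneLibrary:
    def test_error_free_clones_equal_the_amplicon(self):
        p = small(per_clone_error=0.0)
        mat, _, truth = simulate_parents(p)
        clones, truth = simulate_clone_library(mat, PAIRS, p, "maternal", truth)
        templates = {r.id: r.sequence for r in mat}
        for c in clones:
            gene, tid = truth.clone_truth[c.clone_id]
            assert c.sequence in templates[tid]

    def test_counts_per_gene_sum_to_clones_per_gene(self):
        p = small(seed=9)
        mat, _, truth = simulate_parents(p)
        clones, truth = simulate_clone_library(mat, PAIRS, p, "maternal", truth)
        per_gene = {}
        for c in clones:
            gene, _ = truth.clone_truth[c.clone_id]
            per_gene[gene] = per_gene.get(gene, 0) + 1
        assert all(n == p.clones_per_gene for n in per_gene.values())
        assert len(per_gene) == p.n_genes

    def test_infinite_concentration_gives_equal_weights(self):
        """Equal weights in the no-bias limit: counts conserve the clone
        budget and both templates stay near the 15/15 expectation."""
        p = small(amplification_bias_concentration=float("inf"), n_genes=1,
                  clones_per_gene=30, p_loss=0.0)
        mat, _, truth = simulate_parents(p)
        clones, truth = simulate_clone_library(mat, PAIRS, p, "maternal", truth)
        counts = {}
        for c in clones:
            _, tid = truth.clone_truth[c.clone_id]
            counts[tid] = counts.get(tid, 0) + 1
        assert sum(counts.values()) == 30
        # 3 sigma of Binomial(30, 1/2) around 15
        assert all(abs(n - 15) <= 3 * math.sqrt(30 * 0.25) for n in counts.values())

    def test_per_clone_error_matches_binomial_rate(self):
        """Observed per-clone mismatch count vs the template amplicon stays
        within 3 sigma of the binomial expectation."""
        p = SimParams(n_genes=1, clones_per_gene=500, per_clone_error=0.01, seed=13)
        mat, _, truth = simulate_parents(p)
        clones, truth = simulate_clone_library(mat, PAIRS, p, "maternal", truth)
        templates = {r.id: r.sequence[1:] for r in mat}  # amplicon drops base 1
        mismatches = []
        length = None
        for c in clones:
            _, tid = truth.clone_truth[c.clone_id]
            amp = templates[tid]
            length = len(amp)
            mismatches.append(sum(a != b for a, b in zip(c.sequence, amp)))
        mean = np.mean(mismatches)
        expect = p.per_clone_error * length
        sigma = math.sqrt(length * p.per_clone_error * (1 - p.per_clone_error))
        assert abs(mean - expect) < 3 * sigma / math.sqrt(len(mismatches))

    def test_determinism_across_runs(self):
        def build():
            p = small()
            mat, pat, truth = simulate_parents(p)
            hyb, truth = simulate_hybrid(mat, pat, p, truth)
            clones, _ = simulate_clone_library(hyb, PAIRS, p, "hybrid", truth)
            return [(c.clone_id, c.sequence) for c in clones]

        assert build() == build()

    def test_unmatchable_primer_pair_reports_its_name(self):
        from polyhox.seqio import Primer

        p = small()
        mat, _, truth = simulate_parents(p)
        bad = (Primer("noF", "CCCCCCCCCCCCCCCC", "forward"),
               Primer("noR", "GGGGGGGGGGGGGGGG", "reverse"))
        with pytest.raises(ValueError, match="noF/noR"):
            simulate_clone_library(mat, [bad], p, "maternal", truth)
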