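"""In-silico PCR, dereplication and the survey table."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyhox.seqio import CloneRecord, Primer, SeqRecord, iupac_match, reverse_complement
from polyhox.survey import (
    BUILTIN_PRIMER_PAIRS,
    build_survey_table,
    dereplicate_clones,
    insilico_pcr,
)


def concrete(primer: Primer) -> str:
    """One concrete realization of a degenerate primer (first base of each set)."""
    from polyhox.seqio import IUPAC_DNA

    return "".join(sorted(IUPAC_DNA[c] & set("ACGT"))[0] for c in primer.iupac_sequence)


class TestInsilicoPcr:
    def test_homeobox_pair_yields_108bp_product(self, random_dna):
        # the anterior-group homeobox amplicon is 108 bp including primers
        fwd, rev = BUILTIN_PRIMER_PAIRS["PG1-9"]
        insert_len = 108 - len(fwd) - len(rev)
        template = SeqRecord(
            "t",
            random_dna(50) + concrete(fwd) + random_dna(insert_len)
            + reverse_complement(concrete(rev)) + random_dna(50),
        )
        (amp,) = insilico_pcr(template, fwd, rev)
        assert len(amp) == 108
        assert amp.sequence == template.sequence[amp.start - 1 : amp.end]

    def test_template_without_sites_gives_nothing(self, random_dna):
        fwd, rev = BUILTIN_PRIMER_PAIRS["PG1-9"]
        assert insilico_pcr(SeqRecord("t", random_dna(400)), fwd, rev) == []

    def test_two_forward_sites_give_two_products(self, random_dna):
        fwd, rev = BUILTIN_PRIMER_PAIRS["PG9-13"]
        f, r = concrete(fwd), reverse_complement(concrete(rev))
        template = SeqRecord("t", f + random_dna(30) + f + random_dna(40) + r)
        amps = insilico_pcr(template, fwd, rev)
        assert len(amps) == 2
        assert [a.start for a in amps] == sorted(a.start for a in amps)

    def test_max_product_filters_long_pairs(self, random_dna):
        fwd, rev = BUILTIN_PRIMER_PAIRS["HC9a"]
        f, r = concrete(fwd), reverse_complement(concrete(rev))
        template = SeqRecord("t", f + random_dna(300) + r)
        assert insilico_pcr(template, fwd, rev, max_product=200) == []
        assert len(insilico_pcr(template, fwd, rev, max_product=400)) == 1

    @given(st.data())
    def test_agrees_with_bruteforce_scan(self, data):
        """Site pairing equals an independent all-positions scan."""
        import numpy as np

        template_seq = "".join(
            np.random.default_rng(data.draw(st.integers(0, 2**20))).choice(
                list("ACGT"), 2000
            )
        )
        fwd, rev = BUILTIN_PRIMER_PAIRS[data.draw(st.sampled_from(sorted(BUILTIN_PRIMER_PAIRS)))]
        template = SeqRecord("t", template_seq)
        amps = insilico_pcr(template, fwd, rev)

        fpat, rpat = fwd.iupac_sequence, reverse_complement(rev.iupac_sequence)
        expected = []
        for i in range(len(template_seq) - len(fpat) + 1):
            if not all(iupac_match(p, template_seq[i + k]) for k, p in enumerate(fpat)):
                continue
            for j in range(i + len(fpat), len(template_seq) - len(rpat) + 1):
                if not all(iupac_match(p, template_seq[j + k]) for k, p in enumerate(rpat)):
                    continue
                if j + len(rpat) - i <= 5000:
                    expected.append((i + 1, j + len(rpat)))
        assert [(a.start, a.end) for a in amps] == sorted(expected)


def clones_of(seqs: list[str], species="sp") -> list[CloneRecord]:
    return [
        CloneRecord(f"c{i:03d}", species, s, primer_set="HC9a")
        for i, s in enumerate(seqs)
    ]


class TestDereplication:
    def test_singletons_discarded_at_default_support(self, random_dna):
        major = random_dna(120)
        others = [random_dna(120), random_dna(120)]
        variants, discarded = dereplicate_clones(clones_of([major] * 28 + others))
        assert len(variants) == 1 and variants[0].clone_count == 28
        assert len(discarded) == 2

    def test_uniform_library_collapses_to_one_variant(self, random_dna):
        variants, discarded = dereplicate_clones(clones_of([random_dna(100)] * 30))
        assert len(variants) == 1 and discarded == []

    def test_min_support_one_keeps_every_distinct_sequence(self, random_dna):
        seqs = list({random_dna(90) for _ in range(7)})
        variants, discarded = dereplicate_clones(clones_of(seqs), min_support=1)
        assert len(variants) == len(seqs) and discarded == []

    def test_subtype_labels_follow_count_then_sequence(self, random_dna):
        a, b = sorted([random_dna(80), random_dna(80)])
        variants, _ = dereplicate_clones(clones_of([b] * 5 + [a] * 5 + [a[::-1]] * 9))
        assert [v.subtype_label for v in variants] == ["I", "II", "III"]
        assert variants[0].clone_count == 9
        assert (variants[1].sequence, variants[2].sequence) == (a, b)

    def test_mixed_species_rejected(self, random_dna):
        mixed = clones_of([random_dna(80)] * 2) + clones_of([random_dna(80)] * 2, "other")
        with pytest.raises(ValueError):
            dereplicate_clones(mixed)

    @given(st.lists(st.integers(min_value=1, max_value=9), min_size=1, max_size=8),
           st.integers(min_value=1, max_value=4))
    def test_clone_conservation(self, group_sizes, min_support):
        """Sum of variant counts plus discards always equals the input."""
        seqs = []
        for g, size in enumerate(group_sizes):
            tag = "".join("ACGT"[(g >> (2 * k)) & 3] for k in range(4))
            seqs += ["ACGT" * 15 + tag] * size
        variants, discarded = dereplicate_clones(clones_of(seqs), min_support=min_support)
        assert sum(v.clone_count for v in variants) + len(discarded) == len(seqs)
        assert all(v.clone_count >= min_support for v in variants)


class TestSurveyTable:
    def test_totals_are_arithmetic_over_genes(self, random_dna):
        variants, _ = dereplicate_clones(
            clones_of([random_dna(100)] * 10 + [random_dna(100)] * 6
                      + [random_dna(100)] * 14),
            min_support=1,
        )
        variants[0].gene_name = "HoxA5a"
        variants[1].gene_name = "HoxA5a"
        variants[2].gene_name = "HoxC9a"
        table = build_survey_table(variants)
        assert table.loc["Total", "sp_clones"] == 30
        assert table.loc["Total", "sp_variants"] == 3
        assert table.loc["HoxA5a", "sp_variants"] == 2

    def test_empty_input_gives_zero_totals(self):
        table = build_survey_table([])
        assert table.loc["Total"].sum() == 0

    def test_unassigned_variants_get_their_own_row(self, random_dna):
        variants, _ = dereplicate_clones(clones_of([random_dna(100)] * 4), min_support=1)
        table = build_survey_table(variants)
        assert "unassigned" in table.index
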