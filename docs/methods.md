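# Methods

## The analysis problem

An allotetraploid hybrid carries two parental subgenomes. A PCR survey of
its *Hox* loci — short conserved homeobox fragments plus one full-length
exon1–intron–exon2 gene — yields clone libraries for the hybrid and both
parents. The pipeline reconstructs, per locus: which parental subtypes the
hybrid inherited or lost; whether a hybrid copy is a single-breakpoint
chimera of the two parents and where the exchange sits; the gene's
exon/intron organization under the GT-AG rule; and whether a copy has been
pseudogenized by a frameshifting indel. Every stage is validated against a
generative model with a complete event log.

## Core procedures and their assumptions

**Dereplication.** Clones collapse by exact sequence identity; groups with
at least `min_support` clones (default 2) become variants, ordered by
descending clone count then lexicographic sequence and labelled I, II, …
The support threshold operationalizes "sequence many clones to avoid PCR
error": a sequencing/PCR error is overwhelmingly unlikely to recur
identically. On error-free data `min_support=1` is the right setting and is
what the recovery analyses use — there a singleton is a real low-abundance
template, not noise.

**In-silico PCR.** Degenerate primers match under IUPAC set semantics with
a configurable mismatch budget (default 0). Every forward site pairs with
every downstream reverse-complement site up to a product-size cap; amplicons
include both primer footprints, which is how the survey's printed product
sizes (108 bp anterior, 159 bp posterior) count.

**Origin classification.** Percent identity over ungapped columns of a
global alignment (match +1, mismatch −1, gap −2; Biopython's PairwiseAligner
is the engine and its first co-optimal alignment the deterministic
representative). The default threshold is 100%: the survey's fragments are
expected to match their source subgenome exactly, and identity over ungapped
columns deliberately ignores indels so a pseudogenized copy still reports
its parent. A hybrid variant reaching the threshold on one side is labelled
maternal/paternal; on both sides at equal identity, shared (the fragment
cannot distinguish the parents); if both sides tie above the threshold at
different identities the larger side wins (unreachable at the 100% default).
Below threshold on both sides, the recombination screen decides
`recombinant_candidate` vs `novel`. Ancestry fractions count maternal calls
plus half of shared and recombinant calls over all non-novel calls —
a deliberately simple diagnostic-site stand-in for Bayesian admixture
estimation, which is out of scope. "Balanced hybrid" in the symmetry check
means: no losses, no events, and no amplification dropout (bias
concentration → ∞); only then are the counts symmetric by construction and
the fraction exactly ½.

**Recombinant detection.** Informative sites are the columns of the
hybrid/parentA/parentB comparison where the parents disagree and no row is
gapped; the three-way view is built progressively from two pairwise global
alignments projected onto ungapped hybrid coordinates. Sites where the
hybrid matches neither parent are reported separately and excluded from
cost. For both orientations and every cut between consecutive sites, the
cost is the number of sites conflicting with their assigned parent; the
global minimum (ties: A-first orientation, then leftmost cut) is compared
against both zero-switch fits. A call requires the switched fit to beat both
pure fits strictly *and* at least `min_sites_per_side = 2` concordant sites
per flank — a single-site flank is indistinguishable from a point mutation.
The reported interval is the pair of informative sites flanking the cut;
`canonical_prefix_end` (first right-diagnostic position − 1) mirrors the
"1–1026 / 1027–end" partition convention for reporting recombinants. Only
single exchanges are modelled; multi-breakpoint tracts are out of scope.

**Gene-structure inference.** The reference cDNA is globally aligned to the
genomic sequence with a long-gap-friendly affine scheme (open −4, extend
−0.1) so a kilobase intron forms one gap block in the cDNA row; gap blocks
separated by match islands shorter than 15 columns are merged (a diverged
reference bridges an intron with accidental matches). More than one block
above `min_intron = 20` raises an error — single-intron genes only. Each
boundary is then reconfirmed against the GT-AG rule: among GT donors and AG
acceptors within `shift_window = 20` of the alignment's candidate, the pair
whose spliced product has the smallest edit distance to the reference wins;
distance ties (a k-base junction deletion and k mismatching exon-end bases
cost the same in edit distance) re-score under an indel-averse alignment
(gap open −3 > mismatch −1), since a substitution is far likelier than an
indel in a functional exon; remaining ties take the smallest displacement.
The window default of 20 reflects observed junction drift of up to ~15
bases when an exonic indel sits near the boundary; spurious in-window GT/AG
pairs lose on the distance criterion. If no GT-AG pair is reachable the raw
boundaries stand and the model records the rule as unsatisfied.

**Pseudogene calling.** A variant against its functional counterpart:
indels are read off a global alignment (homology floor: ≥ 80% ungapped
identity, else the pair is refused), `net_frameshift` =
(inserted − deleted) mod 3, and all three reading frames are scanned for
internal stops (a stop in a frame's final codon is terminal, not
premature). Verdict: frameshift with an internal stop in *every* frame, or
an in-frame premature stop in frame 0. Stop scanning is only meaningful on
coding sequence, so where a reference cDNA is known the pipeline splices
both variant and counterpart by their own inferred gene models and anchors
the variant's reading frame by trimming its spliced ends to the reference;
short exonic survey fragments are scanned as-is. GC/AT percentages are
computed on counts to two decimals with AT defined as the complement of GC,
so the partition is exactly 100.00.

**Trees.** Kimura two-parameter distances over ungapped columns
(d = −½ ln[(1−2P−Q)√(1−2Q)]; saturated pairs flag infinite distance, capped
at twice the largest finite value inside bootstrap replicates). Neighbor
joining with the Q-criterion, ties broken on the smallest node pair in
creation order; on additive matrices the tree reproduces the input path
distances exactly, which is the test oracle (scikit-bio's NJ is the
independent cross-check). Bootstrap resamples alignment columns and scores
bipartition recurrence, topology only. NJ over K2P replaces
maximum-likelihood tree building deliberately: subtree membership is all the
assignment step needs, and NJ admits an exact oracle.

## The generative model

`SimParams` defaults are the study conditions: 10 loci; 1825 bp genes split
540 / 1075 / 210 (exon1/intron/exon2, echoing the full-length gene's
layout); two duplicated subtypes per parent per locus, 5% apart; 2%
maternal–paternal divergence; 10% each for subtype loss, recombination and
pseudogenization; 30 clones per gene per species; symmetric-Dirichlet
amplification bias (concentration 1.0 — strong bias, as real surveys show);
per-base clone error 0.001 (set to 0 in the recovery analyses). Sites
mutate independently and uniformly (Jukes–Cantor-like); indel lengths are
restricted to {1, 2}, since a 3-base indel does not frameshift.

Biological structure the generator enforces, without which the event log
would not be a sound oracle:

- **Purifying selection.** The spliced exons form a stop-free open reading
  frame (the frame starts at spliced position 3, the one phase in which no
  planted primer footprint can complete a stop codon); substitutions that
  would create a nonsense codon are redrawn among harmless alternatives.
- **Splice sites.** GT/AG dinucleotides are planted at every intron
  boundary and frozen against mutation, as are the primer footprints
  (degenerate positions resolved uniformly once per run).
- **Verified pseudogenization.** An indel is only logged as a pseudogene
  event after checking that the spliced product truncates in every reading
  frame; positions keep 10 bp clear of the splice junctions (a
  junction-proximal indel would disrupt splicing — a different
  pseudogenization route, not modelled) and avoid primer footprints.
- **One event per copy.** Recombination and pseudogenization are mutually
  exclusive draws (p_rec + p_pseudo ≤ 1), so every hybrid copy belongs to
  exactly one event class.

What the generator does *not* emulate: PCR template-switching chimeras,
coalescent genealogies, rate heterogeneity across sites, codon-aware
substitution models, multi-intron genes, and indel evolution in introns.
Passing recovery tests therefore demonstrate the pipeline's correctness
under clean divergence-plus-events data, not robustness to every artifact
of real surveys.

## Truth recovery: what is checked, and what is conditioned away

Recovery analyses run error-free surveys at the defaults and compare every
call with the event log **including the clone-sampling map**: at bias
concentration 1.0 a template regularly draws zero clones, and no analysis
can report on an unsampled copy, so calls about such copies are tallied
"unresolvable" rather than wrong. A chimera must be detected exactly when
(i) both of its parent templates were sampled in their libraries and
(ii) at least `min_sites_per_side` informative sites flank the true
breakpoint — with fewer, single-switch localization is
information-theoretically impossible; these are the detector's stated
applicability bounds, not tuned tolerances. Within those bounds the suite
requires perfection: all origin labels, all detections and orientations,
every reported interval containing the true breakpoint, no recombinant
calls on resolvable non-chimeras, all pseudogene verdicts, and inheritance
reports consistent copy-by-copy.

Problem sizes used by the default test run and the acceptance script: 50
and 12 replicate studies respectively at the full study conditions (10 loci
× 1825 bp × 90 clones), 1 000 random site lists for the breakpoint
brute-force oracle, 200 (tests) / 50 (script) random additive matrices for
the NJ oracle.

## Numerical and convention choices

- Coordinates are 1-based inclusive everywhere; the full-length amplicon
  starts at gene position 2 (the forward footprint sits one base in), so
  gene coordinates and amplicon coordinates differ by one.
- Percent identities and compositions round to two decimals; identity's
  denominator defaults to ungapped columns.
- All simulator randomness flows from one integer seed through named
  per-stage streams (stable across processes); identical seed and
  parameters give byte-identical outputs.
- Degenerate base sets follow IUPAC; primer strings ship with whitespace
  stripped and parenthesized alternatives collapsed to single codes.
- Protein "similarity" is implemented as identity over ungapped columns of
  a +1/0 scored alignment; no substitution-matrix similarity classes.

## Known limitations

- The accession-anchored checks (full-length record lengths, the 1026
  breakpoint, the GT/AG junction positions, the 92.70% spliced-exon
  similarity) require user-exported GenBank FASTA files; the package never
  touches the network, and those checks report what is missing otherwise.
- Clone-level statistics of the original survey (22/19/23 distinct
  fragments per species, per-fragment identities) are not reproducible
  because the underlying clone sequences were not deposited; the synthetic
  recovery suite stands in for them.
- The origin threshold of 100% is right for error-free or well-supported
  variants; at realistic per-clone error rates it should be lowered
  (`identity_threshold`), at the cost of blurring the shared/parental
  distinction.
- Multi-intron genes and multi-breakpoint recombinants are refused loudly
  rather than modelled.
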