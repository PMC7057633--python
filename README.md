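# polyhox

Sequence forensics for *Hox* clone libraries in allopolyploid hybrid fish.

When two species hybridize and the offspring double their genome
(allopolyploidy), the hybrid carries both parental copies — homeologs — of
every locus. PCR surveys of conserved *Hox* homeobox fragments in such a
hybrid and its two parents reveal what happened after genome merger: which
parental subtypes were inherited or lost, which copies became chimeras by
homeologous recombination, and which were silenced by frameshifting indels.
`polyhox` implements that entire analysis as a tested pipeline, built around
the allotetraploid lineage derived from red crucian carp (maternal, RCC) ×
common carp (paternal, CC) and its *HoxC9a* exon1–intron–exon2 locus, and
pairs it with a synthetic clone-library generator that provides ground truth
for every stage.

## What it computes

- **In-silico PCR** with the survey's degenerate primer pairs (IUPAC
  matching; the anterior-group homeobox product is 108 bp, the posterior
  159 bp, the full-length pair brackets a ~1.8 kb gene).
- **Dereplication** of clone libraries into distinct variants with support
  counts, and the gene × species survey table.
- **Parental-origin classification** of each hybrid variant by best
  global-alignment percent identity against both parental panels (default
  threshold 100% — the survey's fragments resolve origin exactly), with
  per-locus inheritance/loss reports and a diagnostic ancestry fraction
  *m̂ = (n_mat + ½·n_shared + ½·n_rec) / n*.
- **Single-breakpoint recombinant detection**: at every informative site
  (parents disagree) the hybrid base votes for one parent; a minimum-cost
  single-switch fit over all cut points and orientations, guarded by a
  two-concordant-sites-per-flank rule, calls the chimera and localizes the
  exchange, which is then annotated against the exon1–intron–exon2 model.
- **GT-AG intron inference** from a genomic vs reference-cDNA alignment,
  with per-boundary splice-site reconfirmation, splicing, translation and
  exon/protein similarity.
- **Pseudogene calling**: frameshifting 1–2 bp indels against the functional
  counterpart plus premature-stop scans over all reading frames, with GC/AT
  composition.
- **Distance trees**: Kimura two-parameter distances, neighbor joining
  (exact on additive matrices), and column-bootstrap bipartition support.
- **Simulator** (`polyhox.simulate`): two diverged parental panels with
  duplicated subtypes per locus, a hybrid with losses / intronic
  recombination / pseudogenizing indels, and Dirichlet-multinomial clone
  libraries with per-base error — every event logged for truth recovery.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
survey (10 loci × 1825 bp, 30 clones per gene per species, error-free
libraries). `python analysis/01_simulate_survey.py` then
`python analysis/04_recombinant_screen.py` prints:

```
4 hybrid variants are single-breakpoint recombinants:
  hybrid.g02-III: maternal (1-723) then paternal (724-end); breakpoint localized to (631, 724), region: intron
  hybrid.g07-II: maternal (1-1099) then paternal (1100-end); breakpoint localized to (990, 1100), region: intron
  hybrid.g09-IV: maternal (1-1094) then paternal (1095-end); breakpoint localized to (986, 1095), region: intron
  hybrid.g10-I: paternal (1-947) then maternal (948-end); breakpoint localized to (845, 948), region: intron
all exchanges localize to the intron — recombination between homeologous chromosomes resolved in the non-coding region
```

Each line reads like the published description of a recombinant gene: the
variant matches one parent up to the canonical prefix end, the other parent
after it, and the breakpoint interval (the two flanking informative sites)
falls inside the intron. `analysis/06_pseudogene_calls.py` prints the
frameshifted copies with premature stops in 3/3 frames and their GC/AT
split, and `analysis/07_truth_recovery.py` scores every call against the
generator's event log (all correct wherever the clone sampling made the
evidence observable).

A CLI mirrors the stages: `polyhox simulate|survey|pcr|recomb|genestruct|
pseudo|tree|report|validate --help`.

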