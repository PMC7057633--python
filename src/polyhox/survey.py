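"""In-silico PCR, clone dereplication and the clone-survey summary table.

The degenerate primer pairs used in the wet-lab survey ship as a built-in
configuration: two homeobox pairs (anterior paralog groups 1-9, posterior
9-13) and the HoxC9a full-length pair.  Degenerate positions are written as
single IUPAC codes (e.g. (C/A) -> M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqio import CloneRecord, IUPAC_DNA, Primer, SeqRecord, reverse_complement

#: Built-in survey primer pairs, as (forward, reverse) `Primer` objects.
BUILTIN_PRIMER_PAIRS: dict[str, tuple[Primer, Primer]] = {
    "PG1-9": (
        Primer("PG1-9F", "GAATTCCACTTCAACMRSTACCT", "forward"),
        Primer("PG1-9R", "CATCCTGCGGTTTTGGAACCANAT", "reverse"),
    ),
    "PG9-13": (
        Primer("PG9-13F", "CGAAAGMGNGTNCCNTAYAC", "forward"),
        Primer("PG9-13R", "CATCCTGCGGTTTTGGAACCANAT", "reverse"),
    ),
    "HC9a": (
        Primer("HC9aF", "ATTATTATGTGGAYTCYTTGAT", "forward"),
        Primer("HC9aR", "TAYTGTTCYTTRCTGTCGTTYT", "reverse"),
    ),
}

_ROMAN = (
    "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI XVII XVIII XIX XX "
    "XXI XXII XXIII XXIV XXV XXVI XXVII XXVIII XXIX XXX XXXI XXXII XXXIII "
    "XXXIV XXXV XXXVI XXXVII XXXVIII XXXIX XL"
).split()


def roman_label(i: int) -> str:
    """1-based Roman-numeral subtype label (I, II, III, ...)."""
    if 1 <= i <= len(_ROMAN):
        return _ROMAN[i - 1]
    return f"sub{i}"


@dataclass(frozen=True)
class Amplicon:
    """A primer-to-primer PCR product on the forward strand of a template.

    ``start``/``end`` are 1-based inclusive template coordinates and the
    sequence includes both primer footprints.
    """

    template_id: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Variant:
    """A dereplicated distinct fragment within one species' library."""

    variant_id: str
    species_label: str
    sequence: str
    clone_count: int
    member_clone_ids: list[str]
    gene_name: str = "unassigned"
    subtype_label: str = ""

    def __post_init__(self):
        if self.clone_count != len(self.member_clone_ids) or self.clone_count < 1:
            raise ValueError(
                f"variant {self.variant_id}: clone_count {self.clone_count} "
                f"!= {len(self.member_clone_ids)} member clones"
            )


def _mismatches(pattern: str, window: str, limit: int) -> int | None:
    """Mismatch count of IUPAC pattern vs concrete window, or None if > limit."""
    mm = 0
    for p, b in zip(pattern, window):
        if b not in IUPAC_DNA.get(p, ()):  # degenerate pattern vs concrete base
            mm += 1
            if mm > limit:
                return None
    return mm


def _pattern_sites(template: str, pattern: str, max_mismatch: int) -> list[int]:
    """0-based start positions where the IUPAC pattern matches the template."""
    k = len(pattern)
    return [
        i
        for i in range(len(template) - k + 1)
        if _mismatches(pattern, template[i : i + k], max_mismatch) is not None
    ]


def insilico_pcr(
    template: SeqRecord,
    forward: Primer,
    reverse: Primer,
    max_mismatch: int = 0,
    max_product: int = 5000,
) -> list[Amplicon]:
    """Enumerate all products of a primer pair on the forward strand.

    Every forward-primer site is paired with every downstream site of the
    reverse primer's reverse complement; products longer than
    ``max_product`` are dropped.  Amplicons include both primer footprints
    and are sorted by (start, end).  No sites -> empty list.
    """
    seq = template.sequence
    f_sites = _pattern_sites(seq, forward.iupac_sequence, max_mismatch)
    r_pattern = reverse_complement(reverse.iupac_sequence)
    r_sites = _pattern_sites(seq, r_pattern, max_mismatch)

    out: list[Amplicon] = []
    for f0 in f_sites:
        f_end = f0 + len(forward)  # 0-based exclusive
        for r0 in r_sites:
            if r0 < f_end:
                continue
            end = r0 + len(r_pattern)  # 0-based exclusive
            if end - f0 > max_product:
                continue
            out.append(Amplicon(template.id, f0 + 1, end, seq[f0:end]))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def dereplicate_clones(
    clones: list[CloneRecord], min_support: int = 2
) -> tuple[list[Variant], list[CloneRecord]]:
    """Collapse clones into distinct variants by exact sequence identity.

    Groups with at least ``min_support`` clones become variants, ordered by
    descending clone count then lexicographic sequence, and labelled with
    Roman-numeral subtypes in that order.  Smaller groups are returned as
    discarded (presumptive PCR/sequencing errors).  Clone conservation:
    sum of variant counts + len(discarded) == len(clones).
    """
    if not clones:
        return [], []
    labels = {c.species_label for c in clones}
    if len(labels) > 1:
        raise ValueError(f"clones mix species labels: {sorted(labels)}")
    species = clones[0].species_label

    groups: dict[str, list[CloneRecord]] = {}
    for c in clones:
        groups.setdefault(c.sequence, []).append(c)

    kept = sorted(
        (g for g in groups.values() if len(g) >= min_support),
        key=lambda g: (-len(g), g[0].sequence),
    )
    variants = [
        Variant(
            variant_id=f"{species}-{roman_label(i)}",
            species_label=species,
            sequence=grp[0].sequence,
            clone_count=len(grp),
            member_clone_ids=[c.clone_id for c in grp],
            subtype_label=roman_label(i),
        )
        for i, grp in enumerate(kept, start=1)
    ]
    discarded = [c for g in groups.values() if len(g) < min_support for c in g]
    return variants, discarded


def build_survey_table(variants: list[Variant]) -> pd.DataFrame:
    """Survey summary: clone and distinct-fragment counts per gene x species.

    Rows are gene names (with a dedicated ``unassigned`` row when present);
    columns are ``<species>_clones`` and ``<species>_variants`` per species
    plus a ``Total`` row.  Per-species clone totals equal the number of
    input clones behind the variants.
    """
    species = sorted({v.species_label for v in variants})
    genes = sorted({v.gene_name for v in variants if v.gene_name != "unassigned"})
    if any(v.gene_name == "unassigned" for v in variants):
        genes.append("unassigned")

    cols: dict[str, dict[str, int]] = {}
    for sp in species:
        clone_col = {g: 0 for g in genes}
        var_col = {g: 0 for g in genes}
        for v in variants:
            if v.species_label != sp:
                continue
            clone_col[v.gene_name] += v.clone_count
            var_col[v.gene_name] += 1
        cols[f"{sp}_clones"] = clone_col
        cols[f"{sp}_variants"] = var_col

    table = pd.DataFrame(cols, index=pd.Index(genes, name="gene"), dtype=int)
    if len(table):
        table.loc["Total"] = table.sum()
    else:
        table = pd.DataFrame(
            0, index=pd.Index(["Total"], name="gene"), columns=list(cols), dtype=int
        )
    return table
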