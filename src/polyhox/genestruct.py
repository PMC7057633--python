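"""Exon1-intron-exon2 gene structure from a genomic vs reference-cDNA
comparison, under the GT-AG spliceosomal rule.

The cDNA is globally aligned to the genomic sequence with a long-gap-friendly
affine scheme so a kilobase intron aligns as a single gap block in the cDNA
row. The largest internal gap block is the intron candidate; each boundary is
then reconfirmed against the GT-AG rule — among nearby GT donors and AG
acceptors, the pair whose spliced product is closest to the reference wins —
the same correction a curator applies when gap placement against a diverged
reference drifts by a few bases at the junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .align_assign import global_align, identity_between, percent_identity
from .seqio import SeqRecord, translate


class GeneStructureError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """Single-intron gene model; 1-based inclusive genomic coordinates."""

    gene_name: str
    exon1: tuple[int, int]
    intron: tuple[int, int]
    exon2: tuple[int, int]
    donor: str
    acceptor: str
    gt_ag_satisfied: bool

    def __post_init__(self):
        if self.exon1[1] + 1 != self.intron[0] or self.intron[1] + 1 != self.exon2[0]:
            raise GeneStructureError("exon/intron coordinates are not contiguous")
        if self.intron[1] < self.intron[0] + 3:
            raise GeneStructureError("intron too short to carry GT...AG")
        if self.gt_ag_satisfied and (self.donor, self.acceptor) != ("GT", "AG"):
            raise GeneStructureError("gt_ag_satisfied but junctions are not GT-AG")

    @property
    def intron_length(self) -> int:
        return self.intron[1] - self.intron[0] + 1


def _gap_blocks(row: str) -> list[tuple[int, int]]:
    """(start, end) 0-based inclusive runs of '-' in an aligned row."""
    blocks = []
    start = None
    for i, ch in enumerate(row):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            blocks.append((start, i - 1))
            start = None
    if start is not None:
        blocks.append((start, len(row) - 1))
    return blocks


def infer_gene_model(
    genomic: SeqRecord,
    reference_cdna: SeqRecord,
    shift_window: int = 20,
    min_intron: int = 20,
) -> GeneModel:
    """Infer the single intron of ``genomic`` relative to a reference cDNA.

    Raises ``GeneStructureError`` when no internal cDNA gap block exists
    ("no intron detected") or when more than one block exceeds
    ``min_intron`` ("multiple introns unsupported").
    """
    if len(genomic) <= len(reference_cdna):
        raise GeneStructureError("genomic sequence must be longer than the cDNA")
    aln = global_align(genomic.sequence, reference_cdna.sequence,
                       match=1.0, mismatch=-1.0, gap=-4.0, gap_extend=-0.1)
    g_row, c_row = aln.aligned_a, aln.aligned_b

    # map alignment columns -> genomic coordinates, then find cDNA gap blocks
    g_pos = []
    p = 0
    for ch in g_row:
        if ch != "-":
            p += 1
        g_pos.append(p)  # genomic position (1-based) at or before this column

    blocks = [
        (s, e) for s, e in _gap_blocks(c_row)
        if s > 0 and e < len(c_row) - 1 and "-" not in g_row[s : e + 1]
    ]
    # A diverged reference can bridge one intron with a few accidental
    # matches, splitting its gap block; islands shorter than merge_island
    # are absorbed into one candidate.
    merge_island = 15
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s - merged[-1][1] - 1 < merge_island:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    blocks = merged
    if not blocks:
        raise GeneStructureError("no intron detected")
    big = [b for b in blocks if b[1] - b[0] + 1 >= min_intron]
    if len(big) > 1:
        raise GeneStructureError("multiple introns unsupported")
    s, e = max(blocks, key=lambda b: b[1] - b[0])
    i_start, i_end = g_pos[s], g_pos[e]  # 1-based genomic intron candidate

    g = genomic.sequence
    L = len(g)

    def junctions(a: int, b: int) -> tuple[str, str]:
        return g[a - 1 : a + 1], g[b - 2 : b]

    # Gap placement against a diverged reference is arbitrary by a few
    # bases (and the two boundaries can drift independently), so each end
    # is reconfirmed separately: among GT donors / AG acceptors within
    # shift_window of the alignment's candidate, keep the pair whose
    # spliced product is closest to the reference (edit distance; ties by
    # smallest displacement). No reachable GT-AG pair leaves the raw
    # candidate with the rule flagged unsatisfied.
    W = shift_window
    ref = reference_cdna.sequence
    gt_pos = [a for a in range(max(2, i_start - W), min(L - 5, i_start + W) + 1)
              if g[a - 1 : a + 1] == "GT"]
    ag_pos = [b for b in range(max(5, i_end - W), min(L - 1, i_end + W) + 1)
              if g[b - 2 : b] == "AG"]
    scored = []
    for a in gt_pos:
        for b in ag_pos:
            if b - a < 3:  # intron must at least hold GT...AG
                continue
            d = edlib.align(g[: a - 1] + g[b:], ref, task="distance")["editDistance"]
            scored.append((d, a, b))
    if scored:
        # Edit distance cannot distinguish "k mismatching exon-end bases"
        # from "k-base deletion at the junction", and ties are common at
        # percent-level reference divergence. A substitution is far likelier
        # than an indel in a functional exon, so ties re-score under an
        # indel-averse alignment; remaining ties go to the smallest move.
        dmin = min(s[0] for s in scored)
        finalists = [s for s in scored if s[0] == dmin]
        if len(finalists) > 1:
            rescored = []
            for _, a, b in finalists:
                aln = global_align(g[: a - 1] + g[b:], ref,
                                   match=1.0, mismatch=-1.0, gap=-3.0, gap_extend=-1.0)
                rescored.append((-aln.score, abs(a - i_start) + abs(b - i_end), a, b))
            _, _, a, b = min(rescored)
        else:
            _, a, b = finalists[0]
        chosen = (a, b)
        satisfied = True
    else:
        chosen = (i_start, i_end)
        satisfied = junctions(*chosen) == ("GT", "AG")

    a, b = chosen
    donor, acceptor = junctions(a, b)
    return GeneModel(
        gene_name=genomic.id,
        exon1=(1, a - 1),
        intron=(a, b),
        exon2=(b + 1, L),
        donor=donor,
        acceptor=acceptor,
        gt_ag_satisfied=satisfied,
    )


def splice(genomic: SeqRecord, model: GeneModel) -> SeqRecord:
    """Excise the intron and ligate exon1 to exon2."""
    g = genomic.sequence
    if model.exon2[1] != len(g):
        raise GeneStructureError("gene model does not span the genomic sequence")
    spliced = g[model.exon1[0] - 1 : model.exon1[1]] + g[model.exon2[0] - 1 : model.exon2[1]]
    return SeqRecord(f"{genomic.id}.cdna", spliced,
                     description=f"spliced intron={model.intron[0]}-{model.intron[1]}")


def similarity_report(
    query_cdna: SeqRecord,
    reference_cdna: SeqRecord,
    query_protein: str | None = None,
    reference_protein: str | None = None,
) -> dict[str, float]:
    """Exon nucleotide identity and protein similarity (identical residues
    over ungapped columns, both to 2 decimals) of a spliced cDNA against the
    reference. Proteins default to frame-0 translations."""
    exon_nt = identity_between(query_cdna.sequence, reference_cdna.sequence)
    qp = query_protein if query_protein is not None else translate(query_cdna.sequence)
    rp = reference_protein if reference_protein is not None else translate(reference_cdna.sequence)
    if not qp or not rp:
        raise ValueError("empty protein sequence")
    if qp == rp:
        prot = 100.0
    else:
        # +1/0 scoring with mild gaps keeps residue columns aligned sensibly
        aln = global_align(qp, rp, match=1.0, mismatch=0.0, gap=-1.0)
        prot = percent_identity(aln)
    return {"exon_nt_identity": exon_nt, "protein_similarity": prot}
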