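"""Pseudogene calling.

A variant is compared with its functional counterpart: frameshifting 1-2 bp
indels are read off the global alignment, all three reading frames are
scanned for premature (internal) stop codons, and base composition is
reported. The operational definition: a frameshifted copy whose every frame
terminates inside the coding region is a pseudogene, as is an in-frame copy
with a premature frame-0 stop.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align_assign import global_align, percent_identity
from .seqio import translate
from .survey import Variant


@dataclass(frozen=True)
class Indel:
    position: int  # 1-based on the counterpart
    length: int
    kind: str  # insertion | deletion (relative to the counterpart)


@dataclass(frozen=True)
class PseudogeneCall:
    variant_id: str
    counterpart_id: str
    indels: tuple[Indel, ...]
    net_frameshift: int  # (inserted - deleted) mod 3
    premature_stop_by_frame: dict[int, int | None]
    is_pseudogene: bool
    gc_percent: float
    at_percent: float


def gc_content(seq: str) -> float:
    """GC percentage of an unambiguous DNA string, to 2 decimals."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    if any(c not in "ACGT" for c in s):
        raise ValueError("ambiguity codes present; GC content ill-defined")
    return round(100.0 * (s.count("G") + s.count("C")) / len(s), 2)


def detect_indels(
    variant_seq: str, counterpart_seq: str, min_identity: float = 80.0
) -> tuple[list[Indel], int]:
    """Indels of the variant relative to its counterpart.

    Sequences must be homologous (>= ``min_identity``% over ungapped
    columns of the global alignment) or the comparison is refused.
    Deletions are positioned at their first deleted counterpart base;
    insertions at the counterpart base they follow (0 = before the start).
    """
    aln = global_align(variant_seq, counterpart_seq, gap=-4.0, gap_extend=-1.0)
    if percent_identity(aln) < min_identity:
        raise ValueError(
            f"sequences not comparable: identity "
            f"{percent_identity(aln):.2f}% < {min_identity:.2f}%"
        )
    indels: list[Indel] = []
    cpos = 0  # counterpart coordinate (1-based after increment)
    run_kind: str | None = None
    run_len = 0
    run_pos = 0
    inserted = deleted = 0

    def flush():
        nonlocal run_kind, run_len
        if run_kind is not None:
            indels.append(Indel(run_pos, run_len, run_kind))
        run_kind, run_len = None, 0

    for v, c in zip(aln.aligned_a, aln.aligned_b):
        if c != "-":
            cpos += 1
        if v == "-" and c != "-":  # base present in counterpart, absent in variant
            deleted += 1
            if run_kind == "deletion":
                run_len += 1
            else:
                flush()
                run_kind, run_len, run_pos = "deletion", 1, cpos
        elif c == "-" and v != "-":
            inserted += 1
            if run_kind == "insertion":
                run_len += 1
            else:
                flush()
                run_kind, run_len, run_pos = "insertion", 1, cpos
        else:
            flush()
    flush()
    return indels, (inserted - deleted) % 3


def scan_premature_stops(seq: str) -> dict[int, int | None]:
    """First internal stop codon (1-based codon index) per reading frame.

    A stop in the final codon of a frame's translation is terminal, not
    premature, and does not count.
    """
    if len(seq) < 6:
        raise ValueError("sequence too short to scan (need >= 6 bases)")
    out: dict[int, int | None] = {}
    for frame in (0, 1, 2):
        aa = translate(seq, frame)
        hit = aa.find("*")
        out[frame] = hit + 1 if 0 <= hit < len(aa) - 1 else None
    return out


def call_pseudogene(variant: Variant, counterpart: Variant) -> PseudogeneCall:
    """Compose indel detection, stop scanning and base composition into a
    pseudogene verdict for one variant/counterpart pair."""
    indels, shift = detect_indels(variant.sequence, counterpart.sequence)
    stops = scan_premature_stops(variant.sequence)
    if shift != 0:
        verdict = all(stops[f] is not None for f in (0, 1, 2))
    else:
        verdict = stops[0] is not None
    gc = gc_content(variant.sequence)
    return PseudogeneCall(
        variant_id=variant.variant_id,
        counterpart_id=counterpart.variant_id,
        indels=tuple(indels),
        net_frameshift=shift,
        premature_stop_by_frame=stops,
        is_pseudogene=verdict,
        gc_percent=gc,
        at_percent=round(100.0 - gc, 2),
    )
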