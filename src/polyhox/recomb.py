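"""Single-breakpoint recombinant detection.

A hybrid sequence is screened against its two parental counterparts: at every
informative site (parents disagree, no gaps) the hybrid base votes for one
parent. A recombinant is called when one switch between parents explains the
votes strictly better than either pure-parent model, with at least
``min_sites_per_side`` concordant sites flanking the switch. The reported
``canonical_prefix_end`` is the last hybrid position attributed to the left
parent under the convention that the switch sits immediately before the first
right-parent-diagnostic site (a 1-1026 / 1027-end style partition).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .align_assign import global_align
from .seqio import SeqRecord


@dataclass(frozen=True)
class InformativeSite:
    """A column where the two parents disagree, in hybrid coordinates."""

    position: int  # 1-based on the ungapped hybrid sequence
    parentA_base: str
    parentB_base: str
    hybrid_base: str
    state: str  # A_like | B_like | neither

    def __post_init__(self):
        if self.parentA_base == self.parentB_base:
            raise ValueError("site is not informative: parents agree")


@dataclass(frozen=True)
class BreakpointCall:
    is_recombinant: bool
    left_parent: str | None
    right_parent: str | None
    interval: tuple[int, int] | None  # (last left-diagnostic, first right-diagnostic)
    canonical_prefix_end: int | None  # first_right_site_position - 1
    switch_cost: int
    zero_switch_costs: tuple[int, int]  # (cost if all-A, cost if all-B)
    neither_sites: int
    region_annotation: str = "unannotated"
    straddles_boundary: bool = False


def _project_to_anchor(anchor: str, other: str) -> list[str | None]:
    """Per ungapped-anchor-position base of ``other`` from a global
    alignment (None where the other row is gapped)."""
    aln = global_align(anchor, other)
    out: list[str | None] = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-":
            out.append(None if y == "-" else y)
    return out


def extract_informative_sites(
    hybrid: SeqRecord, parentA: SeqRecord, parentB: SeqRecord
) -> list[InformativeSite]:
    """Informative sites of the hybrid/parentA/parentB triad.

    The three-way comparison is built progressively with the hybrid as
    anchor (two pairwise global alignments projected onto ungapped hybrid
    coordinates); columns where any row is gapped are dropped.
    """
    for rec in (hybrid, parentA, parentB):
        if not rec.sequence:
            raise ValueError(f"empty sequence {rec.id!r}")
    a_proj = _project_to_anchor(hybrid.sequence, parentA.sequence)
    b_proj = _project_to_anchor(hybrid.sequence, parentB.sequence)
    sites = []
    for idx, (h, a, b) in enumerate(zip(hybrid.sequence, a_proj, b_proj), start=1):
        if a is None or b is None or a == b:
            continue
        state = "A_like" if h == a else ("B_like" if h == b else "neither")
        sites.append(InformativeSite(idx, a, b, h, state))
    return sites


def detect_breakpoint(
    sites: list[InformativeSite],
    labelA: str = "A",
    labelB: str = "B",
    min_sites_per_side: int = 2,
) -> BreakpointCall:
    """Minimum-cost single-switch fit over the informative sites.

    Sites whose hybrid base matches neither parent are excluded from the
    cost and reported separately. For both orientations (A then B, B then A)
    and every cut between consecutive sites (ends included) the cost is the
    number of sites conflicting with their assigned parent; the global best
    (ties: A-first orientation, then leftmost cut) is compared against the
    two zero-switch fits. A recombinant requires the best switched fit to
    beat both pure fits strictly AND each side of the cut to carry at least
    ``min_sites_per_side`` sites concordant with its parent.
    """
    if not sites:
        raise ValueError("no informative sites")
    used = [s for s in sites if s.state != "neither"]
    neither = len(sites) - len(used)
    n = len(used)
    is_a = [1 if s.state == "A_like" else 0 for s in used]
    prefix_a = [0]
    for v in is_a:
        prefix_a.append(prefix_a[-1] + v)
    total_a = prefix_a[-1]
    cost_all_a = n - total_a  # sites voting B under an all-A model
    cost_all_b = total_a

    if n == 0:
        return BreakpointCall(False, None, None, None, None, 0,
                              (cost_all_a, cost_all_b), neither)

    best = None  # (cost, orientation_index, cut)
    for orient, (left_lab, right_lab) in enumerate(((labelA, labelB), (labelB, labelA))):
        for cut in range(n + 1):
            if orient == 0:  # left A, right B
                cost = (cut - prefix_a[cut]) + (prefix_a[n] - prefix_a[cut])
            else:  # left B, right A
                cost = prefix_a[cut] + ((n - cut) - (total_a - prefix_a[cut]))
            cand = (cost, orient, cut)
            if best is None or cand < best:
                best = cand
    cost, orient, cut = best
    left_lab, right_lab = (labelA, labelB) if orient == 0 else (labelB, labelA)

    # concordant support on each side of the selected cut
    if orient == 0:
        left_support = prefix_a[cut]
        right_support = (n - cut) - (total_a - prefix_a[cut])
    else:
        left_support = cut - prefix_a[cut]
        right_support = total_a - prefix_a[cut]

    recomb = (
        cost < min(cost_all_a, cost_all_b)
        and 0 < cut < n
        and left_support >= min_sites_per_side
        and right_support >= min_sites_per_side
    )
    if not recomb:
        return BreakpointCall(False, None, None, None, None, cost,
                              (cost_all_a, cost_all_b), neither)
    interval = (used[cut - 1].position, used[cut].position)
    return BreakpointCall(
        True, left_lab, right_lab, interval, used[cut].position - 1,
        cost, (cost_all_a, cost_all_b), neither,
    )


def annotate_breakpoint(call: BreakpointCall, model=None) -> BreakpointCall:
    """Locate the breakpoint interval in the exon1/intron/exon2 model.

    The annotation is the region holding the interval midpoint; if the
    interval straddles a region boundary the region with the larger share
    wins and a straddle flag is set. No model -> unannotated.
    """
    if model is None or not call.is_recombinant or call.interval is None:
        return call
    regions = {
        "exon1": (model.exon1[0], model.exon1[1]),
        "intron": (model.intron[0], model.intron[1]),
        "exon2": (model.exon2[0], model.exon2[1]),
    }
    lo, hi = call.interval
    shares = {}
    for name, (s, e) in regions.items():
        shares[name] = max(0, min(hi, e) - max(lo, s) + 1)
    covering = [name for name, sh in shares.items() if sh > 0]
    if not covering:
        return replace(call, region_annotation="unannotated")
    best = max(covering, key=lambda nm: (shares[nm], -list(regions).index(nm)))
    return replace(call, region_annotation=best, straddles_boundary=len(covering) > 1)
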