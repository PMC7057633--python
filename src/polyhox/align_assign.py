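"""Alignment, distances, trees and parental-origin classification.

Percent identity drives most calls in the pipeline: a hybrid variant is
attributed to the maternal or paternal subgenome by its best global-alignment
identity against each parental panel (default threshold 100%, i.e. exact
fragment identity, matching how the original survey reads were attributed).
Distance trees use Kimura two-parameter distances with neighbor joining and
nonparametric bootstrap over alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align
from skbio import TreeNode

from .seqio import SeqRecord
from .survey import Variant

# ---------------------------------------------------------------------------
# pairwise alignment and identity


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    aligned_columns: int  # columns where neither row is a gap

    def __post_init__(self):
        assert len(self.aligned_a) == len(self.aligned_b)


def _aligner(match: float, mismatch: float, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = open_gap
    a.extend_gap_score = extend_gap
    return a


def _wrap_alignment(aln) -> PairwiseAlignment:
    ra, rb = str(aln[0]), str(aln[1])
    matches = 0
    cols = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            cols += 1
            if x == y:
                matches += 1
    return PairwiseAlignment(ra, rb, float(aln.score), matches, cols)


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    gap_extend: float | None = None,
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment; linear gaps by default.

    Deterministic: among co-optimal alignments the engine's first is used.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(match, mismatch, gap, gap if gap_extend is None else gap_extend)
    return _wrap_alignment(aligner.align(a.upper(), b.upper())[0])


def percent_identity(alignment: PairwiseAlignment, mode: str = "ungapped_columns") -> float:
    """100 x matches / denominator, to 2 decimals."""
    if mode == "ungapped_columns":
        denom = alignment.aligned_columns
    elif mode == "all_columns":
        denom = len(alignment.aligned_a)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise ValueError("zero denominator: no usable alignment columns")
    return round(100.0 * alignment.matches / denom, 2)


@lru_cache(maxsize=65536)
def _identity_cached(a: str, b: str) -> float:
    return percent_identity(global_align(a, b))


def identity_between(a: str, b: str) -> float:
    """Percent identity of two sequences over ungapped alignment columns
    (exact-equality fast path; memoized, as the classification, inheritance
    and pseudogene stages revisit the same pairs)."""
    if a == b:
        return 100.0
    if a > b:  # identity is symmetric; canonicalize the cache key
        a, b = b, a
    return _identity_cached(a, b)


# ---------------------------------------------------------------------------
# distances and trees

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def kimura2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance over the ungapped columns of two
    aligned rows: d = -1/2 ln((1-2P-Q) sqrt(1-2Q)), with P/Q the transition
    and transversion proportions. Returns ``inf`` when saturated."""
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in _PURINES) == (y in _PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no ungapped columns")
    p, q = ts / n, tv / n
    arg = (1 - 2 * p - q) * math.sqrt(max(0.0, 1 - 2 * q))
    if arg <= 0:
        return math.inf
    return -0.5 * math.log(arg)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if np.any(np.diagonal(self.d) != 0):
            raise ValueError("diagonal must be zero")
        finite = self.d[np.isfinite(self.d)]
        if np.any(finite < 0):
            raise ValueError("distances must be nonnegative")


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining; on an additive matrix the tree's path distances
    reproduce the input exactly.

    Ties in the Q criterion break on the smallest (i, j) pair in node
    creation order (input labels first, then internal nodes as created).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    dmap = {(i, j): dm.d[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))  # node index == creation order

    def dist(i, j):
        return dmap[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                cand = (q, i, j)
                if best is None or cand < best:
                    best = cand
        _, i, j = best
        li = dist(i, j) / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist(i, j) - li
        parent = TreeNode()
        nodes[i].length = float(max(li, 0.0))
        nodes[j].length = float(max(lj, 0.0))
        parent.extend([nodes[i], nodes[j]])
        u = len(nodes)
        nodes.append(parent)
        for k in active:
            if k not in (i, j):
                dmap[(k, u)] = (dist(i, k) + dist(j, k) - dist(i, j)) / 2
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # three-point formulas for the final star
    li = (dist(i, j) + dist(i, k) - dist(j, k)) / 2
    lj = (dist(i, j) + dist(j, k) - dist(i, k)) / 2
    lk = (dist(i, k) + dist(j, k) - dist(i, j)) / 2
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = float(max(ln, 0.0))
        root.append(nodes[idx])
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the smaller-side tip-name sets
    (canonicalized against the full tip set)."""
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        other = tips - side
        out.add(side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other)
    return out


def _k2p_matrix(names: list[str], rows: np.ndarray) -> DistanceMatrix:
    """Pairwise K2P distances over a (n, L) byte matrix of aligned rows.

    Saturated pairs are capped at twice the largest finite distance so the
    agglomeration stays finite.
    """
    n = rows.shape[0]
    acgt = (rows == ord("A")) | (rows == ord("C")) | (rows == ord("G")) | (rows == ord("T"))
    purine = (rows == ord("A")) | (rows == ord("G"))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = acgt[i] & acgt[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError("no ungapped columns for a pair")
            diff = ok & (rows[i] != rows[j])
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            p, q = ts / m, tv / m
            arg = (1 - 2 * p - q) * math.sqrt(max(0.0, 1 - 2 * q))
            d[i, j] = d[j, i] = math.inf if arg <= 0 else -0.5 * math.log(arg)
    if np.isinf(d).any():
        cap = 2.0 * max(1.0, d[np.isfinite(d)].max())
        d[np.isinf(d)] = cap
    return DistanceMatrix(names, d)


def bootstrap_support(
    records: list[SeqRecord], n_reps: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree from an aligned set of sequences with column-bootstrap
    support (percent of replicates containing each internal bipartition,
    topology only). ``n_reps=0`` leaves supports empty."""
    if len(records) < 4:
        raise ValueError("need at least 4 aligned sequences for internal edges")
    L = len(records[0].sequence)
    if any(len(r.sequence) != L for r in records):
        raise ValueError("sequences must be aligned to equal length")
    names = [r.id for r in records]
    rows = np.vstack([np.frombuffer(r.sequence.encode(), dtype=np.uint8) for r in records])

    tree = build_nj_tree(_k2p_matrix(names, rows))
    targets = {}
    tips = frozenset(names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        key = side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other
        targets[key] = node
        node.support = None

    if n_reps <= 0:
        return tree

    rng = np.random.default_rng(seed)
    counts = {k: 0 for k in targets}
    for _ in range(n_reps):
        cols = rng.integers(0, L, L)
        rep = build_nj_tree(_k2p_matrix(names, rows[:, cols]))
        for bp in _bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    for key, node in targets.items():
        node.support = 100.0 * counts[key] / n_reps
        node.name = f"{node.support:.0f}"
    return tree


# ---------------------------------------------------------------------------
# assignment and origin classification


@dataclass(frozen=True)
class OriginCall:
    variant_id: str
    label: str  # maternal | paternal | shared | recombinant_candidate | novel
    best_maternal_identity: float
    best_paternal_identity: float
    best_maternal_match: str | None
    best_paternal_match: str | None
    identity_threshold: float


@dataclass(frozen=True)
class AncestryEstimate:
    maternal_fraction: float
    paternal_fraction: float
    n_diagnostic_sites: int


def _gene_of(rec: SeqRecord) -> str:
    for kv in rec.description.split():
        if kv.startswith("gene="):
            return kv[5:]
    return rec.id


def assign_paralog_group(
    variant: Variant,
    reference_panel: list[SeqRecord],
    floor: float = 60.0,
    prescreen_k: int = 5,
) -> tuple[str, float]:
    """Best-hit gene assignment against a reference panel.

    Candidates are ranked by edit distance (fast bit-parallel prescreen),
    the top ``prescreen_k`` re-scored by global-alignment percent identity;
    ties break on alignment score then lexicographic gene name. Best hits
    below ``floor`` return ("unassigned", best_identity).
    """
    if not reference_panel:
        raise ValueError("reference panel is empty")
    # exact-match fast path
    for rec in reference_panel:
        if rec.sequence == variant.sequence or variant.sequence in rec.sequence:
            return _gene_of(rec), 100.0

    dists = [
        (edlib.align(variant.sequence, rec.sequence, task="distance")["editDistance"], i)
        for i, rec in enumerate(reference_panel)
    ]
    dists.sort()
    cutoff = dists[min(prescreen_k, len(dists)) - 1][0]
    candidates = [reference_panel[i] for dd, i in dists if dd <= cutoff]

    best: tuple[float, float, str] | None = None  # (identity, score, gene)
    for rec in candidates:
        aln = global_align(variant.sequence, rec.sequence)
        cand = (percent_identity(aln), aln.score, _gene_of(rec))
        if (
            best is None
            or cand[:2] > best[:2]
            or (cand[:2] == best[:2] and cand[2] < best[2])
        ):
            best = cand
    gene = best[2] if best[0] >= floor else "unassigned"
    return gene, best[0]


def _best_against(seq: str, panel: list[Variant]) -> tuple[float, str | None]:
    best_id, best_var = -1.0, None
    for v in panel:
        ident = identity_between(seq, v.sequence)
        if ident > best_id:
            best_id, best_var = ident, v.variant_id
    return best_id, best_var


def classify_parental_origin(
    hybrid_variant: Variant,
    maternal_variants: list[Variant],
    paternal_variants: list[Variant],
    identity_threshold: float = 100.0,
    min_sites_per_side: int = 2,
) -> OriginCall:
    """Attribute one hybrid variant to a parental subgenome.

    maternal / paternal: best identity reaches the threshold on that side
    only; shared: both sides reach it at equal identity (the fragment does
    not distinguish the parents); below threshold on both sides, a
    single-breakpoint screen against the best parental pair decides
    recombinant_candidate vs novel.
    """
    if not maternal_variants and not paternal_variants:
        raise ValueError("both parental panels empty")
    bm, bm_id = _best_against(hybrid_variant.sequence, maternal_variants) if maternal_variants else (-1.0, None)
    bp, bp_id = _best_against(hybrid_variant.sequence, paternal_variants) if paternal_variants else (-1.0, None)
    thr = identity_threshold

    if bm >= thr and bp >= thr:
        if abs(bm - bp) < 1e-9:
            label = "shared"
        else:
            label = "maternal" if bm > bp else "paternal"
    elif bm >= thr:
        label = "maternal"
    elif bp >= thr:
        label = "paternal"
    else:
        label = "novel"
        if bm_id is not None and bp_id is not None:
            from .recomb import detect_breakpoint, extract_informative_sites

            mat = next(v for v in maternal_variants if v.variant_id == bm_id)
            pat = next(v for v in paternal_variants if v.variant_id == bp_id)
            sites = extract_informative_sites(
                SeqRecord(hybrid_variant.variant_id, hybrid_variant.sequence),
                SeqRecord("A", mat.sequence),
                SeqRecord("B", pat.sequence),
            )
            if sites:
                call = detect_breakpoint(sites, "maternal", "paternal",
                                         min_sites_per_side=min_sites_per_side)
                if call.is_recombinant:
                    label = "recombinant_candidate"
    return OriginCall(hybrid_variant.variant_id, label, bm, bp, bm_id, bp_id, thr)


def inheritance_report(
    hybrid_variants: list[Variant],
    maternal_variants: list[Variant],
    paternal_variants: list[Variant],
    identity_threshold: float = 100.0,
) -> dict[str, list[str]]:
    """Per-gene retention/loss: a parental subtype is retained iff some
    hybrid variant matches it at >= threshold; hybrid variants matching no
    parental subtype are novel."""
    retained, lost = [], []
    matched_hybrids: set[str] = set()
    for pv in maternal_variants + paternal_variants:
        hit = False
        for hv in hybrid_variants:
            if identity_between(hv.sequence, pv.sequence) >= identity_threshold:
                hit = True
                matched_hybrids.add(hv.variant_id)
        (retained if hit else lost).append(pv.variant_id)
    novel = [hv.variant_id for hv in hybrid_variants if hv.variant_id not in matched_hybrids]
    return {"retained": retained, "lost": lost, "novel": novel}


def estimate_ancestry(origin_calls: list[OriginCall]) -> AncestryEstimate:
    """Diagnostic ancestry fractions over origin-called hybrid variants:
    shared and recombinant_candidate calls contribute half to each parent;
    novel calls are excluded."""
    m = sum(1 for c in origin_calls if c.label == "maternal")
    p = sum(1 for c in origin_calls if c.label == "paternal")
    half = sum(1 for c in origin_calls if c.label in ("shared", "recombinant_candidate"))
    total = m + p + half
    if total == 0:
        raise ValueError("no usable origin calls")
    mf = (m + 0.5 * half) / total
    return AncestryEstimate(mf, 1.0 - mf, total)
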