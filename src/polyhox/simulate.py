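"""Synthetic allopolyploid Hox clone-library simulator.

Emulates the study system: two diverged parental genomes, each carrying two
duplicated subtypes of every Hox locus; an allotetraploid hybrid holding the
union of parental copies minus stochastic losses; occasional single-breakpoint
homeologous recombinants (breakpoint uniform inside the intron); pseudogenizing
1-2 bp exonic indels; and a PCR clone library with Dirichlet-multinomial
amplification bias and independent per-base clone error.

Genes follow an exon1-intron-exon2 layout echoing a full-length fish HoxC9a
locus (540 / 1075 / 210 bp). Functional copies are under purifying selection:
the spliced exons form a stop-free frame-0 open reading frame, and proposed
substitutions that would create a nonsense codon are redrawn. Exact-match
footprints for the built-in survey primer pairs are planted inside the exons
(degenerate positions resolved uniformly once per run, constrained not to
create stop codons), so the full-length pair amplifies essentially the whole
gene and the short homeobox pairs amplify internal 108 / 159 bp fragments.

An indel is only logged as a pseudogenizing event if it in fact introduces a
premature stop in every reading frame of the spliced product (positions are
redrawn until it does), so the event log is a sound oracle for downstream
pseudogene calls.

All randomness flows from a single integer seed; every operation derives an
independent, deterministic stream from it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .seqio import CloneRecord, IUPAC_DNA, Primer, SeqRecord, reverse_complement, translate
from .survey import BUILTIN_PRIMER_PAIRS, insilico_pcr

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {65: 0, 67: 1, 71: 2, 84: 3}
_STOPS = {"TAA", "TAG", "TGA"}
# Spliced 0-based index where the ORF begins. The two bases upstream are
# untranslated; this phase is the one placement where no survey-primer
# footprint can complete a stop codon (the full-length forward footprint
# carries a TGA in its own frame), checked exhaustively over the degenerate
# options at plan time.
_ORF0 = 2


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


@dataclass
class SimParams:
    """Study conditions for one simulated survey.

    Defaults mirror the real design: 10 loci, 1825 bp genes split
    540/1075/210 into exon1/intron/exon2, 2% maternal-paternal divergence,
    5% between within-parent duplicated subtypes, 30 sequenced clones per
    gene, and mild event rates (10% subtype loss / recombination /
    pseudogenization).
    """

    n_genes: int = 10
    exon1_length: int = 540
    intron_length: int = 1075
    exon2_length: int = 210
    parental_divergence: float = 0.02
    subtype_divergence: float = 0.05
    p_loss: float = 0.1
    p_recombinant: float = 0.1
    p_pseudo: float = 0.1
    clones_per_gene: int = 30
    per_clone_error: float = 0.001
    amplification_bias_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("parental_divergence", "subtype_divergence", "p_loss",
                     "p_recombinant", "p_pseudo", "per_clone_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_recombinant + self.p_pseudo > 1.0:
            raise ValueError("p_recombinant + p_pseudo must not exceed 1")
        for name in ("n_genes", "exon1_length", "intron_length", "exon2_length",
                     "clones_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.exon1_length < 30 or self.exon2_length < 30:
            raise ValueError("exons must fit the full-length primer footprints")
        if self.intron_length < 30:
            raise ValueError("intron too short for breakpoint placement")
        if not self.amplification_bias_concentration > 0:
            raise ValueError("amplification_bias_concentration must be positive")

    @property
    def gene_length(self) -> int:
        return self.exon1_length + self.intron_length + self.exon2_length

    @property
    def exon1(self) -> tuple[int, int]:
        """1-based inclusive exon1 interval."""
        return (1, self.exon1_length)

    @property
    def intron(self) -> tuple[int, int]:
        return (self.exon1_length + 1, self.exon1_length + self.intron_length)

    @property
    def exon2(self) -> tuple[int, int]:
        return (self.exon1_length + self.intron_length + 1, self.gene_length)


@dataclass
class SimTruth:
    """Ground-truth event log of one simulated study."""

    gene_layout: dict = field(default_factory=dict)  # exon1/intron/exon2 (1-based)
    copies: dict = field(default_factory=dict)  # copy_id -> {gene, parent, subtype, ...}
    lost_subtypes: list = field(default_factory=list)  # parental copy ids absent from hybrid
    recombination_events: list = field(default_factory=list)
    pseudogene_events: list = field(default_factory=list)
    clone_truth: dict = field(default_factory=dict)  # clone_id -> (gene, template copy id)

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(params: SimParams, *stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed % (2**31), *stream])


def _label_stream(label: str) -> int:
    # stable across processes (unlike hash())
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


def _layout_dict(params: SimParams) -> dict:
    return {"exon1": list(params.exon1), "intron": list(params.intron),
            "exon2": list(params.exon2)}


# ---------------------------------------------------------------------------
# primer footprints


def _spliced_index(params: SimParams) -> np.ndarray:
    """0-based gene positions of the spliced coding sequence, in order."""
    e1, il, L = params.exon1_length, params.intron_length, params.gene_length
    return np.concatenate([np.arange(0, e1), np.arange(e1 + il, L)])


def _footprint_plan(params: SimParams, rng: np.random.Generator) -> list[tuple[int, np.ndarray]]:
    """(gene start0, concrete bases) blocks planted in every template.

    The full-length pair brackets the gene (forward footprint at offset 1 so
    the coding frame stays clean); the short homeobox pairs sit at
    codon-aligned exon offsets giving 108 bp and 159 bp products. Degenerate
    positions resolve uniformly, re-drawn where a choice would complete a
    stop codon in the spliced frame.
    """
    e1, il = params.exon1_length, params.intron_length
    L = params.gene_length
    hf, hr = BUILTIN_PRIMER_PAIRS["HC9a"]
    p19f, p19r = BUILTIN_PRIMER_PAIRS["PG1-9"]
    p913f, p913r = BUILTIN_PRIMER_PAIRS["PG9-13"]

    raw: list[tuple[int, str]] = [
        (1, hf.iupac_sequence),
        (L - len(hr), reverse_complement(hr.iupac_sequence)),
        # canonical splice sites: donor GT opens the intron, acceptor AG
        # closes it; frozen like the primer sites (strong selection)
        (e1, "GT"),
        (e1 + il - 2, "AG"),
    ]
    if e1 >= 230:
        raw.append((99, p19f.iupac_sequence))
        raw.append((207 - len(p19r), reverse_complement(p19r.iupac_sequence)))
    if params.exon2_length >= 181:
        s2 = e1 + il
        raw.append((s2, p913f.iupac_sequence))
        raw.append((s2 + 159 - len(p913r), reverse_complement(p913r.iupac_sequence)))

    # resolve degeneracy
    blocks: list[tuple[int, list[str], list[frozenset[str]]]] = []
    for start0, pattern in raw:
        allowed = [IUPAC_DNA[c] & frozenset("ACGT") for c in pattern]
        concrete = [sorted(a)[rng.integers(0, len(a))] for a in allowed]
        blocks.append((start0, concrete, [frozenset(a) for a in allowed]))

    # forbid stop codons in spliced codons composed entirely of footprint bases
    sp = _spliced_index(params)
    sp_of_gene = {int(g): i for i, g in enumerate(sp)}
    owner: dict[int, tuple[int, int]] = {}  # spliced idx -> (block, offset)
    for bi, (start0, concrete, _) in enumerate(blocks):
        for off in range(len(concrete)):
            g = start0 + off
            if g in sp_of_gene:
                owner[sp_of_gene[g]] = (bi, off)
    for c0 in range(_ORF0, len(sp) - 2, 3):
        idxs = (c0, c0 + 1, c0 + 2)
        if not all(i in owner for i in idxs):
            continue
        def codon():
            return "".join(blocks[owner[i][0]][1][owner[i][1]] for i in idxs)
        guard = 0
        while codon() in _STOPS:
            free = [i for i in idxs if len(blocks[owner[i][0]][2][owner[i][1]]) > 1]
            if not free:
                raise RuntimeError("primer footprint forces a stop codon")  # pragma: no cover
            i = free[int(rng.integers(0, len(free)))]
            bi, off = owner[i]
            opts = sorted(blocks[bi][2][off])
            blocks[bi][1][off] = opts[int(rng.integers(0, len(opts)))]
            guard += 1
            if guard > 100:  # pragma: no cover
                raise RuntimeError("cannot resolve footprint stop codon")
    return [(start0, _to_arr("".join(concrete))) for start0, concrete, _ in blocks]


def _apply_footprints(arr: np.ndarray, blocks) -> np.ndarray:
    out = arr.copy()
    for start0, frag in blocks:
        out[start0 : start0 + frag.size] = frag
    return out


def _frozen_positions(blocks) -> frozenset[int]:
    frozen: set[int] = set()
    for start0, frag in blocks:
        frozen.update(range(start0, start0 + frag.size))
    return frozenset(frozen)


# ---------------------------------------------------------------------------
# coding-aware sequence generation and mutation


def _codon_at(arr: np.ndarray, sp: np.ndarray, c: int) -> str:
    i = _ORF0 + 3 * c
    return _to_str(arr[sp[i : i + 3]])


def _repair_stops(arr: np.ndarray, sp: np.ndarray, frozen: frozenset[int],
                  rng: np.random.Generator) -> None:
    """Redraw free (non-footprint) bases of any stop codon in the spliced
    frame until the ORF is stop-free. In place."""
    n_codons = (sp.size - _ORF0) // 3
    for c in range(n_codons):
        guard = 0
        while _codon_at(arr, sp, c) in _STOPS:
            i = _ORF0 + 3 * c
            pos = [int(p) for p in sp[i : i + 3] if int(p) not in frozen]
            if not pos:  # fully footprint codons handled at plan time
                raise RuntimeError("stop codon with no free position")  # pragma: no cover
            p = pos[int(rng.integers(0, len(pos)))]
            arr[p] = _BASES[int(rng.integers(0, 4))]
            guard += 1
            if guard > 100:  # pragma: no cover
                raise RuntimeError("cannot repair stop codon")


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-site substitution; a hit site takes one of the three
    other bases uniformly. No coding constraint (introns, clone errors)."""
    out = arr.copy()
    if rate <= 0:
        return out
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        idx = np.array([_B2I[b] for b in out[hits]])
        out[hits] = _BASES[(idx + rng.integers(1, 4, hits.size)) % 4]
    return out


def _mutate_coding(arr: np.ndarray, rate: float, rng: np.random.Generator,
                   sp: np.ndarray, codon_of: dict[int, int], blocks) -> np.ndarray:
    """Substitution under purifying selection: primer footprints are
    re-planted after mutation, then any substitution that created a frame-0
    stop in the spliced ORF is redrawn among non-stop alternatives (or
    dropped when none exists)."""
    out = _apply_footprints(_mutate(arr, rate, rng), blocks)
    for p in sorted(codon_of):
        if out[p] == arr[p]:
            continue
        c = codon_of[p]
        if _codon_at(out, sp, c) not in _STOPS:
            continue
        orig = arr[p]
        options = [b for b in _BASES if b != orig]
        rng.shuffle(options)
        for b in options:
            out[p] = b
            if _codon_at(out, sp, c) not in _STOPS:
                break
        else:
            out[p] = orig
    return out


# ---------------------------------------------------------------------------
# the three simulation stages


def simulate_parents(params: SimParams) -> tuple[list[SeqRecord], list[SeqRecord], SimTruth]:
    """Two parental panels, each with 2 duplicated subtypes per locus.

    Per locus: an ancestral sequence whose spliced exons are a stop-free
    ORF; subtype 2 diverges from subtype 1 at ``subtype_divergence``; the
    paternal allele of each subtype diverges from the maternal one at
    ``parental_divergence``. Primer footprints are re-planted after
    mutation so amplification sites stay exact.
    """
    rng = _rng(params, 1)
    blocks = _footprint_plan(params, rng)
    frozen = _frozen_positions(blocks)
    sp = _spliced_index(params)
    n_codons = (sp.size - _ORF0) // 3
    codon_of = {
        int(p): (i - _ORF0) // 3
        for i, p in enumerate(sp)
        if int(p) not in frozen and i >= _ORF0 and (i - _ORF0) < 3 * n_codons
    }
    truth = SimTruth(gene_layout=_layout_dict(params))

    maternal: list[SeqRecord] = []
    paternal: list[SeqRecord] = []
    for g in range(1, params.n_genes + 1):
        gene = f"g{g:02d}"
        ancestral = _apply_footprints(_BASES[rng.integers(0, 4, params.gene_length)], blocks)
        _repair_stops(ancestral, sp, frozen, rng)
        sub2 = _mutate_coding(ancestral, params.subtype_divergence, rng, sp, codon_of, blocks)
        for k, base in ((1, ancestral), (2, sub2)):
            pat = _mutate_coding(base, params.parental_divergence, rng, sp, codon_of, blocks)
            for parent, arr in (("maternal", base), ("paternal", pat)):
                tag = "m" if parent == "maternal" else "p"
                cid = f"{gene}.{tag}{k}"
                rec = SeqRecord(cid, _to_str(arr),
                                description=f"gene={gene} parent={parent} subtype={k}")
                (maternal if parent == "maternal" else paternal).append(rec)
                truth.copies[cid] = {"gene": gene, "parent": parent, "subtype": k}
    return maternal, paternal, truth


def _copy_meta(rec: SeqRecord) -> dict:
    meta = dict(kv.split("=", 1) for kv in rec.description.split())
    meta["subtype"] = int(meta["subtype"])
    return meta


def _splice_plain(seq: str, params: SimParams, e1_shift: int = 0) -> str:
    e1, il = params.exon1_length + e1_shift, params.intron_length
    return seq[:e1] + seq[e1 + il :]


def true_cdna(rec: SeqRecord, params: SimParams) -> SeqRecord:
    """The coding cDNA of an intact full-length gene copy: spliced exons
    from the ORF start (frame 0 = the gene's reading frame). Serves as the
    structure/pseudogene reference, like a published cDNA would."""
    return SeqRecord(
        f"{rec.id}.cdna",
        _splice_plain(rec.sequence, params)[_ORF0:],
        description=rec.description,
    )


def _pseudogenizes(variant_seq: str, params: SimParams, pos: int, delta: int) -> bool:
    """True iff the indel copy's spliced product carries a premature stop
    in every reading frame (``pos``/``delta``: indel site and signed length
    on the original coordinates)."""
    e1 = params.exon1_length
    spliced = _splice_plain(variant_seq, params, e1_shift=delta if pos <= e1 else 0)
    spliced = spliced[_ORF0:]  # the frame the full-length amplicon exposes
    for frame in (0, 1, 2):
        aa = translate(spliced, frame)
        hit = aa.find("*")
        if not (0 <= hit < len(aa) - 1):
            return False
    return True


def simulate_hybrid(
    maternal_panel: list[SeqRecord],
    paternal_panel: list[SeqRecord],
    params: SimParams,
    truth: SimTruth | None = None,
) -> tuple[list[SeqRecord], SimTruth]:
    """Allotetraploid panel: union of parental copies minus losses, with
    single-breakpoint homeologous chimeras and pseudogenizing indels.

    Per surviving copy, at most one event (mutually exclusive draw): with
    probability ``p_recombinant`` the copy is replaced by a chimera
    switching to its homeolog (same locus and subtype, other parent) at a
    breakpoint uniform inside the intron; else with probability
    ``p_pseudo`` it receives a 1-2 bp indel at a uniform exon position
    clear of primer footprints and splice junctions, redrawn until the
    spliced product truncates in every reading frame. Events replace
    copies, they never add new ones.
    """
    if not maternal_panel or not paternal_panel:
        raise ValueError("parental panels must be non-empty")
    rng = _rng(params, 2)
    blocks = _footprint_plan(params, _rng(params, 1))  # same plan as simulate_parents
    frozen = _frozen_positions(blocks)
    if truth is None:
        truth = SimTruth(gene_layout=_layout_dict(params))

    by_id = {r.id: r for r in maternal_panel + paternal_panel}
    homeolog = {}
    for rec in by_id.values():
        m = _copy_meta(rec)
        other = "p" if m["parent"] == "maternal" else "m"
        homeolog[rec.id] = f"{m['gene']}.{other}{m['subtype']}"

    i0, i1 = params.intron  # 1-based inclusive
    margin = 10  # keep indels clear of the splice junctions
    exon_ok = np.array([
        p for p in range(1, params.gene_length + 1)
        if not (i0 - margin <= p <= i1 + margin) and (p - 1) not in frozen
        and p > margin and p <= params.gene_length - margin
    ])

    hybrid: list[SeqRecord] = []
    for rec in maternal_panel + paternal_panel:
        meta = _copy_meta(rec)
        cid = f"4n.{rec.id}"
        if rng.random() < params.p_loss:
            truth.lost_subtypes.append(rec.id)
            continue
        u = rng.random()
        seq = rec.sequence
        note = "intact"
        if u < params.p_recombinant:
            partner = by_id[homeolog[rec.id]]
            b = int(rng.integers(i0, i1 + 1))  # last position from the left parent
            seq = rec.sequence[:b] + partner.sequence[b:]
            truth.recombination_events.append({
                "gene": meta["gene"], "copy_id": cid,
                "left_parent": rec.id, "right_parent": partner.id,
                "true_breakpoint_position": b, "region": "intron",
            })
            note = "recombinant"
        elif u < params.p_recombinant + params.p_pseudo:
            kind = "insertion" if rng.random() < 0.5 else "deletion"
            length = int(rng.integers(1, 3))
            for _attempt in range(200):
                if kind == "deletion":
                    ok = exon_ok if length == 1 else exon_ok[np.isin(exon_ok + 1, exon_ok)]
                    pos = int(ok[rng.integers(0, ok.size)])
                    cand = seq[: pos - 1] + seq[pos - 1 + length :]
                    delta = -length
                else:
                    pos = int(exon_ok[rng.integers(0, exon_ok.size)])
                    ins = _to_str(_BASES[rng.integers(0, 4, length)])
                    cand = seq[:pos] + ins + seq[pos:]
                    delta = length
                if _pseudogenizes(cand, params, pos, delta):
                    break
            else:  # pragma: no cover - astronomically unlikely at real sizes
                raise RuntimeError("could not place a pseudogenizing indel")
            seq = cand
            truth.pseudogene_events.append({
                "gene": meta["gene"], "copy_id": cid,
                "indel_position": pos, "indel_length": length, "indel_kind": kind,
            })
            note = "pseudogene"
        hybrid.append(SeqRecord(cid, seq, description=f"{rec.description} event={note}"))
        truth.copies[cid] = {"gene": meta["gene"], "parent": meta["parent"],
                             "subtype": meta["subtype"], "source": rec.id, "event": note}
    return hybrid, truth


def simulate_clone_library(
    panel: list[SeqRecord],
    primer_pairs: Sequence[tuple[Primer, Primer]],
    params: SimParams,
    species_label: str,
    truth: SimTruth | None = None,
) -> tuple[list[CloneRecord], SimTruth]:
    """PCR clone library over a panel.

    For each locus and primer pair, template weights are drawn from a
    symmetric Dirichlet (``amplification_bias_concentration``; ``inf``
    means exactly equal weights) and ``clones_per_gene`` clones are
    multinomial over templates. Each clone is its template's amplicon with
    independent per-base errors at ``per_clone_error``. Truth maps every
    clone to its template copy.
    """
    if truth is None:
        truth = SimTruth(gene_layout=_layout_dict(params))
    rng = _rng(params, 3, _label_stream(species_label))

    by_gene: dict[str, list[SeqRecord]] = {}
    for rec in panel:
        by_gene.setdefault(_copy_meta(rec)["gene"], []).append(rec)

    clones: list[CloneRecord] = []
    counter = 0
    for fwd, rev in primer_pairs:
        pair_name = f"{fwd.name}/{rev.name}"
        any_site = False
        for gene in sorted(by_gene):
            templates, amplicons = [], []
            for rec in by_gene[gene]:
                amps = insilico_pcr(rec, fwd, rev)
                if amps:
                    templates.append(rec)
                    amplicons.append(amps[0].sequence)
            if not templates:
                continue
            any_site = True
            k = len(templates)
            conc = params.amplification_bias_concentration
            if np.isinf(conc):
                weights = np.full(k, 1.0 / k)
            else:
                weights = rng.dirichlet(np.full(k, conc))
            counts = rng.multinomial(params.clones_per_gene, weights)
            for tmpl, amp, n in zip(templates, amplicons, counts):
                arr = _to_arr(amp)
                for _ in range(n):
                    counter += 1
                    cid = f"{species_label}.c{counter:05d}"
                    clones.append(CloneRecord(
                        cid, species_label,
                        _to_str(_mutate(arr, params.per_clone_error, rng)),
                        primer_set=pair_name,
                    ))
                    truth.clone_truth[cid] = (gene, tmpl.id)
        if not any_site:
            raise ValueError(f"no primer site for pair {pair_name} on any template")
    return clones, truth
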