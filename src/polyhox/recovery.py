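"""Ground-truth recovery harness over the simulator.

Runs the full pipeline on an error-free simulated clone survey and scores
every downstream call against the simulator's event log. The expectations
are derived from the truth *including the clone-sampling map*: a gene copy
that drew no clones under amplification bias is invisible to any analysis,
so calls about it are tallied as unresolvable rather than wrong, and a
chimera is only required to be detected when both of its parent templates
were sampled and the breakpoint has at least ``min_sites_per_side``
diagnostic sites on each flank — with fewer, no single-switch method can
localize the exchange.
"""

from __future__ import annotations

from dataclasses import replace

from .pipeline import PipelineConfig, _assign_and_relabel, _dereplicate_role, analyze
from .seqio import SeqRecord
from .simulate import (
    SimParams,
    simulate_clone_library,
    simulate_hybrid,
    simulate_parents,
    true_cdna,
)
from .survey import BUILTIN_PRIMER_PAIRS, Variant


def simulate_survey(params: SimParams):
    """One full synthetic study: parental panels, hybrid genome, and
    full-length clone libraries for all three species."""
    mat, pat, truth = simulate_parents(params)
    hyb, truth = simulate_hybrid(mat, pat, params, truth)
    pairs = [BUILTIN_PRIMER_PAIRS["HC9a"]]
    clones = {}
    for label, panel in (("hybrid", hyb), ("maternal", mat), ("paternal", pat)):
        clones[label], truth = simulate_clone_library(panel, pairs, params, label, truth)
    return clones, {"maternal": mat, "paternal": pat, "hybrid": hyb}, truth


def _informative_positions(a: str, b: str) -> list[int]:
    """1-based positions where two equal-length sequences differ."""
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


def run_recovery(seed: int, min_sites_per_side: int = 2, **overrides) -> dict:
    """Pipeline-vs-truth scorecard for one simulated study.

    Defaults to the study conditions with ``per_clone_error=0`` and
    dereplication at ``min_support=1`` (with no clone error a singleton is
    a real template, not noise).
    """
    params = SimParams(seed=seed, per_clone_error=0.0, **overrides)
    clones, panels, truth = simulate_survey(params)
    panel = panels["maternal"] + panels["paternal"]
    ref_cdna = {
        r.id.split(".")[0]: true_cdna(r, params)
        for r in panels["maternal"]
        if r.id.endswith(".m1")
    }
    cfg = PipelineConfig(min_support=1, min_sites_per_side=min_sites_per_side, seed=seed)
    report = analyze(
        clones["hybrid"], clones["maternal"], clones["paternal"],
        reference_panel=panel, reference_cdna_by_gene=ref_cdna, config=cfg,
    )

    by_id = {r.id: r for r in panel + panels["hybrid"]}
    sampled = {
        role: {truth.clone_truth[c.clone_id][1] for c in clones[role]}
        for role in ("hybrid", "maternal", "paternal")
    }
    side_of = {"maternal": "maternal", "paternal": "paternal"}

    # hybrid variant -> template copy ids (via its member clones)
    hyb_variants, _ = _dereplicate_role(clones["hybrid"], 1)
    hyb_variants = _assign_and_relabel(hyb_variants, "hybrid", panel, cfg.assignment_floor)
    var_templates = {
        v.variant_id: sorted({truth.clone_truth[c][1] for c in v.member_clone_ids})
        for v in hyb_variants
    }

    recomb_by_copy = {e["copy_id"]: e for e in truth.recombination_events}
    pseudo_by_copy = {e["copy_id"]: e for e in truth.pseudogene_events}

    tally = {
        "seed": seed,
        "n_hybrid_variants": len(hyb_variants),
        "gene_assignment": {"total": 0, "correct": 0},
        "origin": {"evaluable": 0, "correct": 0, "unresolvable": 0, "ambiguous": 0},
        "recomb": {
            "true_chimeras_sampled": 0, "eligible": 0, "detected": 0,
            "orientation_correct": 0, "interval_contains_truth": 0,
            "detected_total": len(report["breakpoint_calls"]),
            "false_positive_resolvable": 0, "ineligible": 0,
        },
        "pseudo": {"evaluable": 0, "correct": 0, "uncalled": 0},
        "inheritance": {"copies": 0, "consistent": 0, "mismatches": []},
        "ancestry": report["ancestry"],
    }

    for v in hyb_variants:
        templates = var_templates[v.variant_id]
        if len(templates) != 1:
            tally["origin"]["ambiguous"] += 1
            continue
        copy_id = templates[0]
        meta = truth.copies[copy_id]
        event = meta["event"]
        side = side_of[meta["parent"]]

        tally["gene_assignment"]["total"] += 1
        if v.gene_name == meta["gene"]:
            tally["gene_assignment"]["correct"] += 1

        call = report["origin_calls"].get(v.variant_id)
        src = meta["source"]
        src_sampled = src in sampled[side]

        if event in ("intact", "pseudogene"):
            if src_sampled and call is not None:
                tally["origin"]["evaluable"] += 1
                # identical to its source: expect that side (or shared when the
                # fragment happens to match the other side too)
                if call["label"] in (side, "shared"):
                    tally["origin"]["correct"] += 1
                if call["label"] == "recombinant_candidate":
                    tally["recomb"]["false_positive_resolvable"] += 1
            else:
                tally["origin"]["unresolvable"] += 1
        else:  # recombinant
            ev = recomb_by_copy[copy_id]
            partner = ev["right_parent"]
            other = "paternal" if side == "maternal" else "maternal"
            b = ev["true_breakpoint_position"]
            diffs = _informative_positions(
                by_id[src].sequence, by_id[partner].sequence
            )
            left_sites = sum(1 for p in diffs if p <= b)
            right_sites = len(diffs) - left_sites
            eligible = (
                src in sampled[side]
                and partner in sampled[other]
                and left_sites >= min_sites_per_side
                and right_sites >= min_sites_per_side
            )
            tally["recomb"]["true_chimeras_sampled"] += 1
            if not eligible:
                tally["recomb"]["ineligible"] += 1
            else:
                tally["recomb"]["eligible"] += 1
                bp = report["breakpoint_calls"].get(v.variant_id)
                if call is not None and call["label"] == "recombinant_candidate" and bp:
                    tally["recomb"]["detected"] += 1
                    if bp["left_parent"] == side:
                        tally["recomb"]["orientation_correct"] += 1
                    # truth position is in gene coordinates; the full-length
                    # amplicon drops gene base 1
                    b_amp = b - 1
                    lo, hi = bp["interval"]
                    if lo <= b_amp < hi:
                        tally["recomb"]["interval_contains_truth"] += 1

        # pseudogene verdicts are unconditional on parental sampling: the
        # spliced ORF criterion needs only some same-gene counterpart
        pcall = report["pseudogene_calls"].get(v.variant_id)
        if event in ("intact", "pseudogene"):
            expected = event == "pseudogene"
            if pcall is None or "is_pseudogene" not in pcall:
                tally["pseudo"]["uncalled"] += 1
            else:
                tally["pseudo"]["evaluable"] += 1
                if pcall["is_pseudogene"] == expected:
                    tally["pseudo"]["correct"] += 1

    # inheritance: each parental copy should be reported retained iff some
    # sampled hybrid variant still matches it exactly (modulo indels)
    par_variants = {}
    for role in ("maternal", "paternal"):
        vs, _ = _dereplicate_role(clones[role], 1)
        vs = _assign_and_relabel(vs, role, panel, cfg.assignment_floor)
        for pv in vs:
            tmpl = {truth.clone_truth[c][1] for c in pv.member_clone_ids}
            if len(tmpl) == 1:
                par_variants[pv.variant_id] = (role, next(iter(tmpl)))

    reported_lost = {
        vid for gene_rep in report["inheritance"].values() for vid in gene_rep["lost"]
    }
    reported_retained = {
        vid for gene_rep in report["inheritance"].values() for vid in gene_rep["retained"]
    }
    for vid, (role, copy_id) in par_variants.items():
        hyb_copy = f"4n.{copy_id}"
        meta = truth.copies.get(hyb_copy)
        if meta is None:
            expect = "lost"  # lost from the hybrid genome
        elif hyb_copy not in sampled["hybrid"]:
            expect = "lost"  # present but invisible to the survey
        elif meta["event"] in ("intact", "pseudogene"):
            expect = "retained"  # exact match, or indel invisible to ungapped identity
        else:  # chimera: retained only if the chimera still equals the source
            ev = recomb_by_copy[hyb_copy]
            diffs = _informative_positions(
                by_id[copy_id].sequence, by_id[ev["right_parent"]].sequence
            )
            changed = any(p > ev["true_breakpoint_position"] for p in diffs)
            expect = "lost" if changed else "retained"
        got = ("lost" if vid in reported_lost
               else "retained" if vid in reported_retained else "absent")
        tally["inheritance"]["copies"] += 1
        if got == expect:
            tally["inheritance"]["consistent"] += 1
        else:
            tally["inheritance"]["mismatches"].append(
                {"parental_variant": vid, "copy": copy_id,
                 "expected": expect, "reported": got}
            )
    return tally
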