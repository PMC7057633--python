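"""End-to-end orchestration: survey -> assignment -> origin/inheritance ->
recombination screen -> gene structure -> pseudogene calls -> ancestry.

`analyze` is the in-memory engine; `run_pipeline` wraps it with file I/O and
a consolidated JSON + TSV report; `validate_against_accessions` reruns the
full-length HoxC9a comparisons on user-exported GenBank records (the package
never touches the network).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .align_assign import (
    OriginCall,
    assign_paralog_group,
    classify_parental_origin,
    estimate_ancestry,
    identity_between,
    inheritance_report,
)
from .genestruct import GeneModel, GeneStructureError, infer_gene_model, similarity_report, splice
from .pseudo import PseudogeneCall, call_pseudogene
from .recomb import annotate_breakpoint, detect_breakpoint, extract_informative_sites
from .seqio import CloneRecord, SeqRecord, read_clone_table, read_fasta
from .survey import Variant, build_survey_table, dereplicate_clones, roman_label


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run; every threshold the
    stages use is surfaced here and recorded in the report provenance."""

    hybrid_clones: str | None = None
    maternal_clones: str | None = None
    paternal_clones: str | None = None
    reference_panel: str | None = None
    reference_cdna: str | None = None
    full_length: str | None = None  # genomic records for gene-structure work
    out_dir: str = "polyhox_out"
    min_support: int = 2
    identity_threshold: float = 100.0
    min_sites_per_side: int = 2
    assignment_floor: float = 60.0
    bootstrap_reps: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.min_support < 1 or self.min_sites_per_side < 1:
            raise ValueError("support thresholds must be >= 1")
        if not (0 <= self.identity_threshold <= 100 and 0 <= self.assignment_floor <= 100):
            raise ValueError("identity thresholds are percentages in [0, 100]")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be nonnegative")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _dereplicate_role(
    clones: list[CloneRecord], min_support: int
) -> tuple[list[Variant], list[CloneRecord]]:
    """Dereplicate one species' library, primer set by primer set."""
    variants: list[Variant] = []
    discarded: list[CloneRecord] = []
    by_primer: dict[str, list[CloneRecord]] = {}
    for c in clones:
        by_primer.setdefault(c.primer_set, []).append(c)
    for pset in sorted(by_primer):
        vs, dis = dereplicate_clones(by_primer[pset], min_support=min_support)
        variants.extend(vs)
        discarded.extend(dis)
    return variants, discarded


def _assign_and_relabel(
    variants: list[Variant],
    species: str,
    reference_panel: list[SeqRecord] | None,
    floor: float,
) -> list[Variant]:
    """Assign variants to genes (best hit against the panel) and relabel
    subtypes I, II, ... within each (species, gene), by descending clone
    count then lexicographic sequence."""
    for v in variants:
        if reference_panel:
            gene, _ident = assign_paralog_group(v, reference_panel, floor=floor)
            v.gene_name = gene
    by_gene: dict[str, list[Variant]] = {}
    for v in variants:
        by_gene.setdefault(v.gene_name, []).append(v)
    out: list[Variant] = []
    for gene in sorted(by_gene):
        group = sorted(by_gene[gene], key=lambda v: (-v.clone_count, v.sequence))
        for i, v in enumerate(group, start=1):
            v.subtype_label = roman_label(i)
            v.variant_id = f"{species}.{gene}-{v.subtype_label}"
            out.append(v)
    return out


def _trim_to_reference(seq: str, ref_seq: str) -> str:
    """Drop the ends of ``seq`` that overhang the reference in a global
    alignment, anchoring position 1 (and hence frame 0) to the reference."""
    from .align_assign import global_align

    aln = global_align(seq, ref_seq)
    b = aln.aligned_b
    i0 = len(b) - len(b.lstrip("-"))
    i1 = len(b.rstrip("-"))
    return aln.aligned_a[i0:i1].replace("-", "")


def _spliced_variant(
    variant: Variant, reference_cdna: SeqRecord
) -> tuple[Variant, GeneModel] | None:
    """Splice a (presumed full-length genomic) variant by its own inferred
    gene model, in the reading frame of the reference cDNA; None when no
    intron is detectable."""
    rec = SeqRecord(variant.variant_id.replace(" ", "_"), variant.sequence)
    try:
        model = infer_gene_model(rec, reference_cdna)
    except GeneStructureError:
        return None
    cdna = _trim_to_reference(splice(rec, model).sequence, reference_cdna.sequence)
    v = Variant(
        variant_id=variant.variant_id, species_label=variant.species_label,
        sequence=cdna, clone_count=variant.clone_count,
        member_clone_ids=list(variant.member_clone_ids),
        gene_name=variant.gene_name, subtype_label=variant.subtype_label,
    )
    return v, model


def analyze(
    hybrid_clones: list[CloneRecord],
    maternal_clones: list[CloneRecord],
    paternal_clones: list[CloneRecord],
    reference_panel: list[SeqRecord] | None = None,
    reference_cdna_by_gene: dict[str, SeqRecord] | None = None,
    full_length: list[SeqRecord] | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every analysis stage in memory and return the report dict.

    Variants are grouped by assigned gene (or by primer set when no
    reference panel is given); hybrid variants are origin-classified
    against the parental variants of their group; candidates failing both
    parents are screened for a single breakpoint; where a reference cDNA is
    known for a gene, pseudogene calls are made on spliced coding sequence,
    otherwise on the raw fragment.
    """
    cfg = config or PipelineConfig()
    roles = {}
    derep_stats = {}
    for role, clones in (("hybrid", hybrid_clones), ("maternal", maternal_clones),
                         ("paternal", paternal_clones)):
        if not clones:
            roles[role] = []
            derep_stats[role] = {"clones_in": 0, "variants": 0, "discarded": 0}
            continue
        variants, discarded = _dereplicate_role(clones, cfg.min_support)
        species = clones[0].species_label
        variants = _assign_and_relabel(
            variants, species, reference_panel, cfg.assignment_floor
        )
        roles[role] = variants
        derep_stats[role] = {
            "clones_in": len(clones),
            "variants": len(variants),
            "discarded": len(discarded),
        }

    all_variants = [v for vs in roles.values() for v in vs]
    survey = build_survey_table(all_variants)

    def groups_of(variants: list[Variant]) -> dict[str, list[Variant]]:
        out: dict[str, list[Variant]] = {}
        for v in variants:
            out.setdefault(v.gene_name, []).append(v)
        return out

    hyb_groups = groups_of(roles["hybrid"])
    mat_groups = groups_of(roles["maternal"])
    pat_groups = groups_of(roles["paternal"])

    origin_calls: dict[str, OriginCall] = {}
    inheritance: dict[str, dict] = {}
    breakpoint_calls: dict[str, dict] = {}
    genes = sorted(set(hyb_groups) | set(mat_groups) | set(pat_groups))
    for gene in genes:
        hv = hyb_groups.get(gene, [])
        mv = mat_groups.get(gene, [])
        pv = pat_groups.get(gene, [])
        if hv and (mv or pv):
            inheritance[gene] = inheritance_report(hv, mv, pv, cfg.identity_threshold)
        for v in hv:
            if not (mv or pv):
                continue
            call = classify_parental_origin(
                v, mv, pv, cfg.identity_threshold, cfg.min_sites_per_side
            )
            origin_calls[v.variant_id] = call
            if call.label == "recombinant_candidate":
                mat = next(x for x in mv if x.variant_id == call.best_maternal_match)
                pat = next(x for x in pv if x.variant_id == call.best_paternal_match)
                sites = extract_informative_sites(
                    SeqRecord("h", v.sequence),
                    SeqRecord("A", mat.sequence),
                    SeqRecord("B", pat.sequence),
                )
                bp = detect_breakpoint(sites, "maternal", "paternal",
                                       cfg.min_sites_per_side)
                model = None
                if reference_cdna_by_gene and gene in reference_cdna_by_gene:
                    spliced = _spliced_variant(v, reference_cdna_by_gene[gene])
                    model = spliced[1] if spliced else None
                bp = annotate_breakpoint(bp, model)
                side = {"maternal": call.best_maternal_match,
                        "paternal": call.best_paternal_match}
                breakpoint_calls[v.variant_id] = {
                    **asdict(bp),
                    "left_parent_variant": side.get(bp.left_parent),
                    "right_parent_variant": side.get(bp.right_parent),
                }

    # gene structure on supplied full-length genomic records
    gene_models: dict[str, dict] = {}
    structure_reports: dict[str, dict] = {}
    if full_length and reference_cdna_by_gene:
        for rec in full_length:
            gene = _gene_label(rec)
            ref = reference_cdna_by_gene.get(gene)
            if ref is None and len(reference_cdna_by_gene) == 1:
                ref = next(iter(reference_cdna_by_gene.values()))
            if ref is None:
                continue
            try:
                model = infer_gene_model(rec, ref)
            except GeneStructureError as exc:
                structure_reports[rec.id] = {"error": str(exc)}
                continue
            cdna = splice(rec, model)
            gene_models[rec.id] = asdict(model)
            structure_reports[rec.id] = similarity_report(cdna, ref)

    # pseudogene calls: hybrid variants against their best parental counterpart
    pseudo_calls: dict[str, dict] = {}
    for gene in genes:
        counterparts = mat_groups.get(gene, []) + pat_groups.get(gene, [])
        if not counterparts:
            continue
        ref = (reference_cdna_by_gene or {}).get(gene)
        spliced_cache: dict[str, Variant | None] = {}

        def spliced_of(v: Variant) -> Variant | None:
            """Coding sequence of a variant: spliced by its own model when a
            reference cDNA is known (None if no model is inferable — a raw
            intron-containing sequence would make stop scanning meaningless),
            the raw fragment otherwise (exonic survey amplicons)."""
            if ref is None:
                return v
            if v.variant_id not in spliced_cache:
                got = _spliced_variant(v, ref)
                spliced_cache[v.variant_id] = got[0] if got else None
            return spliced_cache[v.variant_id]

        for v in hyb_groups.get(gene, []):
            best = max(counterparts,
                       key=lambda c: identity_between(v.sequence, c.sequence))
            vs_cds, best_cds = spliced_of(v), spliced_of(best)
            if vs_cds is None or best_cds is None:
                pseudo_calls[v.variant_id] = {
                    "variant_id": v.variant_id, "counterpart_id": best.variant_id,
                    "error": "no gene model inferable; pseudogene status not called",
                }
                continue
            try:
                call = call_pseudogene(vs_cds, best_cds)
            except ValueError:
                continue  # not comparable at the homology floor
            pseudo_calls[v.variant_id] = _pseudo_dict(call)

    ancestry = None
    usable = [c for c in origin_calls.values() if c.label != "novel"]
    if usable:
        est = estimate_ancestry(list(origin_calls.values()))
        ancestry = asdict(est)

    report = {
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "thresholds": {
                "min_support": cfg.min_support,
                "identity_threshold": cfg.identity_threshold,
                "min_sites_per_side": cfg.min_sites_per_side,
                "assignment_floor": cfg.assignment_floor,
            },
        },
        "dereplication": derep_stats,
        "survey": survey.reset_index().to_dict(orient="records"),
        "variants": [
            {"variant_id": v.variant_id, "species": v.species_label,
             "gene": v.gene_name, "subtype": v.subtype_label,
             "clone_count": v.clone_count, "length": len(v.sequence)}
            for v in all_variants
        ],
        "origin_calls": {k: asdict(c) for k, c in origin_calls.items()},
        "inheritance": inheritance,
        "breakpoint_calls": breakpoint_calls,
        "gene_models": gene_models,
        "structure_reports": structure_reports,
        "pseudogene_calls": pseudo_calls,
        "ancestry": ancestry,
    }
    return report


def _pseudo_dict(call: PseudogeneCall) -> dict:
    d = asdict(call)
    d["premature_stop_by_frame"] = {str(k): v for k, v in call.premature_stop_by_frame.items()}
    return d


def _gene_label(rec: SeqRecord) -> str:
    for kv in rec.description.split():
        if kv.startswith("gene="):
            return kv[5:]
    return rec.id


def run_pipeline(config: PipelineConfig) -> dict:
    """File-to-file pipeline run: read clone tables / FASTA inputs, run
    `analyze`, write ``report.json`` plus TSV summaries under
    ``config.out_dir`` and return the report."""

    def load_clones(path: str | None) -> list[CloneRecord]:
        if path is None:
            return []
        if str(path).endswith((".tsv", ".txt")):
            return read_clone_table(path)
        species = Path(path).stem
        return [
            CloneRecord(r.id, species, r.sequence, primer_set="unknown")
            for r in read_fasta(path)
        ]

    panel = read_fasta(config.reference_panel) if config.reference_panel else None
    cdna_by_gene = None
    if config.reference_cdna:
        cdna_by_gene = {_gene_label(r): r for r in read_fasta(config.reference_cdna)}
    full = read_fasta(config.full_length) if config.full_length else None

    report = analyze(
        load_clones(config.hybrid_clones),
        load_clones(config.maternal_clones),
        load_clones(config.paternal_clones),
        reference_panel=panel,
        reference_cdna_by_gene=cdna_by_gene,
        full_length=full,
        config=config,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    pd.DataFrame(report["survey"]).to_csv(out / "survey.tsv", sep="\t", index=False)
    pd.DataFrame(report["variants"]).to_csv(out / "variants.tsv", sep="\t", index=False)
    if report["origin_calls"]:
        pd.DataFrame(report["origin_calls"].values()).to_csv(
            out / "origin_calls.tsv", sep="\t", index=False
        )
    return report


# ---------------------------------------------------------------------------
# accession validation

ACCESSIONS = {
    "MN584925": "RCC HoxC9a genomic",
    "MN584926": "CC HoxC9a genomic",
    "MN584927": "4nAT HoxC9a genomic (recombinant)",
    "BC165307": "zebrafish HoxC9a cDNA",
}

PRINTED = {
    "length_MN584925": 1837,
    "length_MN584926": 1834,
    "length_MN584927": 1835,
    "recomb_prefix_end": 1026,
    "recomb_left_parent": "CC",
    "donor_g_position": 539,
    "acceptor_g_position": 1616,
    "exon_similarity_4nAT_vs_zebrafish": 92.70,
}


def _find_accession(fasta_dir: str | Path, accession: str) -> SeqRecord | None:
    d = Path(fasta_dir)
    for pattern in (f"{accession}.fasta", f"{accession}.fa"):
        p = d / pattern
        if p.exists():
            recs = read_fasta(p)
            if recs:
                return recs[0]
    for p in sorted(list(d.glob("*.fasta")) + list(d.glob("*.fa"))):
        for rec in read_fasta(p):
            if accession in rec.id or accession in rec.description:
                return rec
    return None


def validate_against_accessions(fasta_dir: str | Path) -> pd.DataFrame:
    """Recompute the full-length HoxC9a checks from user-exported GenBank
    FASTA files and tabulate computed vs printed values.

    Rows cover the three genomic lengths, the recombination triad (4nAT vs
    CC/RCC: left parent and 1-based prefix end), the GT donor / AG acceptor
    G positions of the 4nAT intron against the zebrafish cDNA, and the
    spliced-exon similarity. Missing exports yield 'skipped' rows naming
    the absent accession.
    """
    recs = {acc: _find_accession(fasta_dir, acc) for acc in ACCESSIONS}
    rows: list[dict] = []

    def add(check: str, computed, printed, needs: list[str]):
        missing = [a for a in needs if recs[a] is None]
        if missing:
            rows.append({"check": check, "computed": None, "printed": printed,
                         "status": f"skipped (missing {', '.join(missing)})"})
            return
        ok = computed == printed if not isinstance(printed, float) else (
            abs(float(computed) - printed) < 0.005
        )
        rows.append({"check": check, "computed": computed, "printed": printed,
                     "status": "match" if ok else "MISMATCH"})

    for acc in ("MN584925", "MN584926", "MN584927"):
        rec = recs[acc]
        add(f"length_{acc}", len(rec) if rec else None, PRINTED[f"length_{acc}"], [acc])

    if all(recs[a] for a in ("MN584925", "MN584926", "MN584927")):
        sites = extract_informative_sites(
            recs["MN584927"], recs["MN584926"], recs["MN584925"]
        )
        call = detect_breakpoint(sites, "CC", "RCC")
        add("recomb_left_parent", call.left_parent, PRINTED["recomb_left_parent"],
            ["MN584925", "MN584926", "MN584927"])
        add("recomb_prefix_end", call.canonical_prefix_end,
            PRINTED["recomb_prefix_end"], ["MN584925", "MN584926", "MN584927"])
    else:
        add("recomb_left_parent", None, PRINTED["recomb_left_parent"],
            ["MN584925", "MN584926", "MN584927"])
        add("recomb_prefix_end", None, PRINTED["recomb_prefix_end"],
            ["MN584925", "MN584926", "MN584927"])

    if recs["MN584927"] and recs["BC165307"]:
        try:
            model = infer_gene_model(recs["MN584927"], recs["BC165307"])
            add("donor_g_position", model.intron[0], PRINTED["donor_g_position"],
                ["MN584927", "BC165307"])
            add("acceptor_g_position", model.intron[1] - 1,
                PRINTED["acceptor_g_position"], ["MN584927", "BC165307"])
            sim = similarity_report(splice(recs["MN584927"], model), recs["BC165307"])
            add("exon_similarity_4nAT_vs_zebrafish", sim["exon_nt_identity"],
                PRINTED["exon_similarity_4nAT_vs_zebrafish"], ["MN584927", "BC165307"])
        except GeneStructureError as exc:
            rows.append({"check": "gene_structure", "computed": str(exc),
                         "printed": "GT-AG intron", "status": "MISMATCH"})
    else:
        for check in ("donor_g_position", "acceptor_g_position",
                      "exon_similarity_4nAT_vs_zebrafish"):
            add(check, None, PRINTED[check], ["MN584927", "BC165307"])

    return pd.DataFrame(rows)
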