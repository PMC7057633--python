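#!/usr/bin/env python
"""Simulate the clone survey: two parental Hox panels (2 duplicated subtypes
per locus), an allotetraploid hybrid with losses / homeologous recombinants /
pseudogenizing indels, and error-free full-length clone libraries for all
three species. Writes panels, clone tables and the ground-truth event log."""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SIM_DIR, load_study

from polyhox.seqio import write_clone_table, write_fasta


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    params, clones, panels, _, ref_cdna, truth = load_study(args.seed)
    SIM_DIR.mkdir(parents=True, exist_ok=True)
    for label, panel in panels.items():
        write_fasta(panel, SIM_DIR / f"{label}_panel.fasta")
        if label in clones:
            write_clone_table(clones[label], SIM_DIR / f"{label}_clones.tsv")
    write_fasta(ref_cdna.values(), SIM_DIR / "reference_cdna.fasta")
    (SIM_DIR / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2) + "\n")

    print(f"study seed {args.seed}: {params.n_genes} loci of {params.gene_length} bp "
          f"(exons {params.exon1_length}+{params.exon2_length}, intron {params.intron_length})")
    print(f"hybrid genome: {len(panels['hybrid'])} copies "
          f"({len(truth.lost_subtypes)} parental subtypes lost, "
          f"{len(truth.recombination_events)} recombinants, "
          f"{len(truth.pseudogene_events)} pseudogenized)")
    for label in ("maternal", "paternal", "hybrid"):
        print(f"  {label} library: {len(clones[label])} clones")
    print(f"wrote panels, clone tables, reference cDNAs and truth.json to {SIM_DIR}")


if __name__ == "__main__":
    main()
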