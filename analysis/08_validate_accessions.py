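#!/usr/bin/env python
"""Computed-vs-printed checks on the deposited full-length HoxC9a records
(user-exported GenBank FASTA under data/accessions/; see the README there).
Reports which exports are missing instead of fetching anything."""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from polyhox.pipeline import validate_against_accessions

ACCESSION_DIR = Path(__file__).resolve().parent.parent / "data" / "accessions"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fasta-dir", type=Path, default=ACCESSION_DIR)
    args = ap.parse_args()

    table = validate_against_accessions(args.fasta_dir)
    out = RESULTS / "accession_validation.tsv"
    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False)
    print(table.to_string(index=False))
    n_skip = sum(str(s).startswith("skipped") for s in table["status"])
    if n_skip:
        print(f"\n{n_skip}/{len(table)} checks skipped — export the records "
              f"listed above to {args.fasta_dir} to run them.")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
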