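#!/usr/bin/env python
"""Screen hybrid variants that match neither parent exactly for a single
exchange between the parental sequences, localize each breakpoint from the
informative sites, and place it in the exon1-intron-exon2 model."""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_report


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    report = load_report(args.seed)
    calls = report["breakpoint_calls"]
    out = RESULTS / "breakpoint_calls.json"
    out.write_text(json.dumps(calls, indent=2, sort_keys=True) + "\n")

    print(f"{len(calls)} hybrid variants are single-breakpoint recombinants:")
    for vid, bp in sorted(calls.items()):
        lo, hi = bp["interval"]
        print(f"  {vid}: {bp['left_parent']} (1-{bp['canonical_prefix_end']}) then "
              f"{bp['right_parent']} ({bp['canonical_prefix_end'] + 1}-end); "
              f"breakpoint localized to ({lo}, {hi}), region: {bp['region_annotation']}")
    regions = {bp["region_annotation"] for bp in calls.values()}
    if regions <= {"intron"} and calls:
        print("all exchanges localize to the intron — recombination between "
              "homeologous chromosomes resolved in the non-coding region")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
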