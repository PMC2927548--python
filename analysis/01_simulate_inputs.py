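#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Builds the two-genome scenario (driver/passenger pair adjacent in one genome,
separated by an inversion in the other), simulates tumor cohorts under the
proximity model, paired tumor/normal exon reads, a repeat annotation over the
breakpoint interval, triplicate Ct tables, and an aCGH profile with 4% of the
genome altered.  Everything lands under results/data/.
"""

import argparse
from pathlib import Path

from xenopass import cli


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    rc = cli.main(["simulate", "--outdir", str(args.outdir), "--seed", str(args.seed)])
    if rc == 0:
        n_reads = len(list((args.outdir / "reads").glob("*.fasta")))
        print(f"wrote ortholog table, truth mutations, {n_reads} read pairs, "
              f"repeats, Ct table and aCGH profile to {args.outdir}")
    return rc


if __name__ == "__main__":
    raise SystemExit(main())
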