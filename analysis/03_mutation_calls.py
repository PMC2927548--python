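#!/usr/bin/env python
"""Tumor/normal mutation calling over the simulated read sets.

Runs the quality-trimming -> consensus -> alignment -> Q20-filtered calling
chain on the FASTA+QUAL pairs written by 01_simulate_inputs.py, then compares
per-gene truncating prevalence between the two species' cohorts.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from xenopass import cli

GENOMES = ("human_like", "mouse_like")


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/mutcall"))
    args = parser.parse_args()

    rc = cli.main(
        ["mutcall", "--reads", str(args.datadir / "reads"),
         "--exons", str(args.datadir / "exons.tsv"), "--outdir", str(args.outdir)]
    )
    if rc != 0:
        return rc

    calls = pd.read_csv(args.outdir / "variant_calls.tsv", sep="\t")
    summary = json.loads((args.outdir / "cohort_summary.json").read_text())
    print(f"sequencing success rate: {summary['success_rate_pct']}% "
          f"({summary['successes']}/{summary['attempts']} reads)")
    if calls.empty:
        print("no variant calls")
        return 0
    calls["species"] = calls["sample"].str.rsplit("_", n=1).str[0]
    truncating = calls[calls["effect"].isin(["nonsense", "frameshift"])]
    prev = (
        truncating.groupby(["species", "gene"])["sample"].nunique().unstack(fill_value=0)
    )
    print("tumors with a truncating lesion, by species and gene:")
    print(prev.to_string())
    prev.to_csv(args.outdir / "truncating_prevalence.tsv", sep="\t")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
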