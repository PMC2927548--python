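#!/usr/bin/env python
"""Synteny landscape of the simulated genome pair.

Reads the ortholog table written by 01_simulate_inputs.py, builds synteny
blocks, locates rearrangement breakpoints, measures the driver/passenger
gene-pair distance in each genome, and reports repeat coverage of the
breakpoint interval between the pair.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from xenopass import io as xio
from xenopass import synteny as syn

GENOMES = ("human_like", "mouse_like")
PAIR = ("DRV1", "PSG1")


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/synteny"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    omap = xio.read_ortholog_table(args.datadir / "orthologs.tsv")
    blocks = syn.build_synteny_blocks(omap, *GENOMES)
    breakpoints = syn.find_breakpoints(blocks, GENOMES[0])

    distances = {g: syn.gene_pair_distance(*PAIR, g, omap) for g in GENOMES}
    repeats = xio.read_bed(args.datadir / "repeats.bed")
    drv = omap.locus(PAIR[0], GENOMES[0])
    psg = omap.locus(PAIR[1], GENOMES[0])
    bp_interval = ("chr1", drv.end, psg.start)
    density_total = syn.repeat_density(bp_interval, repeats)
    density_alu = syn.repeat_density(bp_interval, repeats, family="Alu")

    pd.DataFrame(
        [{"block": i, "orientation": b.orientation, "genes": ",".join(b.genes)}
         for i, b in enumerate(blocks)]
    ).to_csv(args.outdir / "blocks.tsv", sep="\t", index=False)
    xio.write_bed(
        pd.DataFrame([{"chrom": b.chrom, "start": b.start, "end": b.end} for b in breakpoints]),
        args.outdir / "breakpoints.bed",
    )
    report = {
        "n_blocks": len(blocks),
        "n_breakpoints": len(breakpoints),
        "pair_distance_bp": distances,
        "breakpoint_repeat_density": {"total": density_total, "alu": density_alu},
    }
    xio.write_json(report, args.outdir / "landscape.json")

    print(f"{len(blocks)} synteny blocks, {len(breakpoints)} breakpoints on {GENOMES[0]}")
    print(f"{PAIR[0]}-{PAIR[1]} distance: "
          f"{distances[GENOMES[0]]/1e3:.0f} kb in {GENOMES[0]}, "
          f"{distances[GENOMES[1]]/1e6:.1f} Mb in {GENOMES[1]}")
    print(f"breakpoint interval repeat coverage: {density_total:.2f} total, {density_alu:.2f} Alu")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
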