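"""Synteny blocks, rearrangement breakpoints and gene-pair distances.

Two genomes that share orthologous genes are compared purely through gene
*order and orientation*: a synteny block is a maximal run of shared genes that
is consecutive and colinear in both genomes (order preserved with uniform
orientation, or uniformly reversed with flipped strands).  Gaps between
adjacent blocks on a chosen reference genome are rearrangement breakpoints.

Coordinates are 0-based half-open throughout this module; file readers in
:mod:`xenopass.io` convert from 1-based inclusive tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: Sentinel distance for gene pairs on different chromosomes.  Using infinity
#: makes distance-decay terms exp(-d/lambda) vanish naturally.
UNLINKED = math.inf


@dataclass(frozen=True)
class GeneLocus:
    """Location of one gene in one genome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid locus {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class OrthologMap:
    """Per-genome coordinates of a shared gene set.

    Parameters
    ----------
    loci
        ``{gene_id: {genome_id: GeneLocus}}``.  A gene may be present in only
        a subset of genomes (singletons are excluded from synteny blocks but
        reported by :meth:`singletons`).
    """

    def __init__(self, loci: Mapping[str, Mapping[str, GeneLocus]]):
        self._loci: dict[str, dict[str, GeneLocus]] = {
            g: dict(per) for g, per in loci.items()
        }
        for gene, per in self._loci.items():
            if not per:
                raise ValueError(f"gene {gene!r} present in no genome")

    # -- access -----------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self._loci)

    @property
    def genomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for per in self._loci.values():
            for g in per:
                seen.setdefault(g, None)
        return list(seen)

    def locus(self, gene: str, genome: str) -> GeneLocus:
        try:
            per = self._loci[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in ortholog map") from None
        try:
            return per[genome]
        except KeyError:
            raise KeyError(f"gene {gene!r} absent from genome {genome!r}") from None

    def has(self, gene: str, genome: str) -> bool:
        return genome in self._loci.get(gene, {})

    def shared_genes(self, genome_a: str, genome_b: str) -> list[str]:
        return [g for g, per in self._loci.items() if genome_a in per and genome_b in per]

    def singletons(self, genome_a: str, genome_b: str) -> list[str]:
        """Genes present in exactly one of the two genomes."""
        return [
            g
            for g, per in self._loci.items()
            if (genome_a in per) != (genome_b in per)
        ]

    def genes_in(self, genome: str) -> list[str]:
        return [g for g, per in self._loci.items() if genome in per]

    # -- (de)serialisation --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": gene,
                "genome": genome,
                "chrom": loc.chrom,
                "start": loc.start,
                "end": loc.end,
                "strand": loc.strand,
            }
            for gene, per in self._loci.items()
            for genome, loc in per.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "genome", "chrom", "start", "end", "strand"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrthologMap":
        loci: dict[str, dict[str, GeneLocus]] = {}
        for row in frame.itertuples(index=False):
            per = loci.setdefault(row.gene_id, {})
            if row.genome in per:
                raise ValueError(
                    f"gene {row.gene_id!r} appears more than once in genome {row.genome!r}"
                )
            per[row.genome] = GeneLocus(str(row.chrom), int(row.start), int(row.end), str(row.strand))
        return cls(loci)


@dataclass(frozen=True)
class SyntenyBlock:
    """Maximal colinear run of shared genes between two genomes."""

    genes: tuple[str, ...]
    intervals: Mapping[str, tuple[str, int, int]]  # genome -> (chrom, start, end)
    orientation: str  # 'same' | 'inverted'

    def interval(self, genome: str) -> tuple[str, int, int]:
        return self.intervals[genome]


@dataclass(frozen=True)
class Breakpoint:
    """Interval between the bounding genes of two adjacent blocks."""

    genome: str
    chrom: str
    start: int
    end: int
    left_block: int
    right_block: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionInstabilityReport:
    chrom: str
    start: int
    end: int
    flank: int
    per_species: Mapping[str, int]
    supporting_species: int
    min_species: int
    verdict: str  # 'stable' | 'unstable'


def _order_index(map_: OrthologMap, genes: Iterable[str], genome: str) -> dict[str, tuple[str, int]]:
    """Gene -> (chrom, within-chromosome rank) for the given genome.

    Ranks start at 1 so that signed ranks are never ambiguous at zero.
    """
    loci = [(g, map_.locus(g, genome)) for g in genes]
    loci.sort(key=lambda item: (item[1].chrom, item[1].start))
    out: dict[str, tuple[str, int]] = {}
    rank = 0
    prev_chrom = None
    for gene, loc in loci:
        if loc.chrom != prev_chrom:
            rank = 0
            prev_chrom = loc.chrom
        rank += 1
        out[gene] = (loc.chrom, rank)
    return out


def build_synteny_blocks(map_: OrthologMap, genome_a: str, genome_b: str) -> list[SyntenyBlock]:
    """Partition the genes shared by two genomes into maximal colinear blocks.

    Walking genes in ``genome_a`` order, a block is extended while the next
    gene sits on the same chromosome pair and its signed rank in ``genome_b``
    (negative when the strand flips between genomes) increases by exactly one
    — the classic signed-permutation run criterion.  Genes present in only one
    genome are ignored here (see :meth:`OrthologMap.singletons`).
    """
    shared = map_.shared_genes(genome_a, genome_b)
    if not shared:
        warnings.warn(f"no genes shared by {genome_a!r} and {genome_b!r}", stacklevel=2)
        return []

    order_a = _order_index(map_, shared, genome_a)
    order_b = _order_index(map_, shared, genome_b)
    genes_sorted = sorted(shared, key=lambda g: order_a[g])

    def signed_b(gene: str) -> int:
        sign = 1 if map_.locus(gene, genome_a).strand == map_.locus(gene, genome_b).strand else -1
        return sign * order_b[gene][1]

    runs: list[list[str]] = []
    current = [genes_sorted[0]]
    for prev, nxt in zip(genes_sorted, genes_sorted[1:]):
        contiguous = (
            order_a[prev][0] == order_a[nxt][0]
            and order_a[nxt][1] == order_a[prev][1] + 1
            and order_b[prev][0] == order_b[nxt][0]
            and signed_b(nxt) == signed_b(prev) + 1
        )
        if contiguous:
            current.append(nxt)
        else:
            runs.append(current)
            current = [nxt]
    runs.append(current)

    blocks: list[SyntenyBlock] = []
    for run in runs:
        orientation = "same"
        if len(run) >= 1 and signed_b(run[0]) < 0:
            orientation = "inverted"
        intervals: dict[str, tuple[str, int, int]] = {}
        for genome in (genome_a, genome_b):
            locs = [map_.locus(g, genome) for g in run]
            intervals[genome] = (
                locs[0].chrom,
                min(l.start for l in locs),
                max(l.end for l in locs),
            )
        blocks.append(SyntenyBlock(tuple(run), intervals, orientation))
    return blocks


def find_breakpoints(blocks: list[SyntenyBlock], reference: str) -> list[Breakpoint]:
    """Breakpoints between adjacent blocks on the reference genome.

    Blocks are maximal, so any two blocks adjacent on a reference chromosome
    are non-colinear on the other genome; the breakpoint interval is the gap
    between the bounding genes of the two blocks (intergenic by construction).
    """
    indexed = sorted(
        range(len(blocks)), key=lambda i: (blocks[i].interval(reference)[0], blocks[i].interval(reference)[1])
    )
    out: list[Breakpoint] = []
    for left, right in zip(indexed, indexed[1:]):
        chrom_l, _, end_l = blocks[left].interval(reference)
        chrom_r, start_r, _ = blocks[right].interval(reference)
        if chrom_l != chrom_r:
            continue
        out.append(
            Breakpoint(
                genome=reference,
                chrom=chrom_l,
                start=min(end_l, start_r),
                end=max(end_l, start_r),
                left_block=left,
                right_block=right,
            )
        )
    return out


def gene_pair_distance(gene_a: str, gene_b: str, genome: str, map_: OrthologMap) -> float:
    """Start-to-start distance (bp) between two genes in one genome.

    Returns :data:`UNLINKED` (infinity) when the genes sit on different
    chromosomes.  Symmetric in its gene arguments.
    """
    loc_a = map_.locus(gene_a, genome)
    loc_b = map_.locus(gene_b, genome)
    if loc_a.chrom != loc_b.chrom:
        return UNLINKED
    return float(abs(loc_a.start - loc_b.start))


def classify_region_instability(
    region: tuple[str, int, int],
    breakpoints_by_species: Mapping[str, Iterable[Breakpoint]],
    min_species: int = 3,
    flank: int = 5_000_000,
) -> RegionInstabilityReport:
    """Call a region evolutionarily unstable when enough species break in/near it.

    A species supports instability when at least one of its breakpoints
    intersects ``region`` widened by ``flank`` on both sides; the region is
    *unstable* when ``>= min_species`` species support it.
    """
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    chrom, start, end = region
    lo, hi = start - flank, end + flank
    per_species: dict[str, int] = {}
    for species, bps in breakpoints_by_species.items():
        n = sum(1 for bp in bps if bp.chrom == chrom and bp.end > lo and bp.start < hi)
        per_species[species] = n
    supporting = sum(1 for n in per_species.values() if n > 0)
    verdict = "unstable" if supporting >= min_species else "stable"
    return RegionInstabilityReport(
        chrom=chrom,
        start=start,
        end=end,
        flank=flank,
        per_species=per_species,
        supporting_species=supporting,
        min_species=min_species,
        verdict=verdict,
    )


def repeat_density(
    interval: tuple[str, int, int],
    repeats: pd.DataFrame,
    family: str | None = None,
) -> float:
    """Fraction of interval bases covered by repeat records (union coverage).

    ``repeats`` is a BED-style frame with columns ``chrom, start, end`` and an
    optional ``family`` column used when ``family`` is given.  Malformed
    records (start >= end, missing fields) are skipped with a warning.
    """
    chrom, start, end = interval
    if end <= start:
        raise ValueError("interval length must be > 0")
    spans: list[tuple[int, int]] = []
    skipped = 0
    for row in repeats.itertuples(index=False):
        try:
            r_chrom, r_start, r_end = str(row.chrom), int(row.start), int(row.end)
        except (ValueError, TypeError, AttributeError):
            skipped += 1
            continue
        if r_start >= r_end:
            skipped += 1
            continue
        if r_chrom != chrom:
            continue
        if family is not None and getattr(row, "family", None) != family:
            continue
        lo, hi = max(r_start, start), min(r_end, end)
        if lo < hi:
            spans.append((lo, hi))
    if skipped:
        warnings.warn(f"skipped {skipped} malformed repeat records", stacklevel=2)
    if not spans:
        return 0.0
    spans.sort()
    covered = 0
    cur_lo, cur_hi = spans[0]
    for lo, hi in spans[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return covered / (end - start)
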