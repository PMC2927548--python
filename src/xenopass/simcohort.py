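"""Synthetic data generators for every stage of the cross-species pipeline.

These simulators define the study conditions the rest of the package is
validated against: two rearrangement-related genomes in which a gene pair is
adjacent in one genome and distant in the other; repeat-rich breakpoint
intervals; tumor cohorts mutated under a distance-decay proximity model;
Sanger-like paired reads with phred-calibrated error injection; triplicate
qPCR Ct tables; and 5-kb-spaced aCGH log2-ratio profiles with a few percent
of the genome altered.

All randomness flows from integer seeds through numpy Generators; identical
seeds give identical outputs.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mutcall import TraceRead, revcomp
from .synteny import UNLINKED, GeneLocus, OrthologMap, gene_pair_distance

_BASES = "ACGT"
_STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# genomes and rearrangements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RearrangementEvent:
    """One structural event applied to the derived genome.

    Inversions reverse gene order within ``[start, end)`` and flip contained
    strands; translocations move the genes of the source interval to
    ``dest_chrom:dest_pos`` preserving relative offsets.
    """

    kind: str  # 'inversion' | 'translocation'
    chrom: str
    start: int
    end: int
    dest_chrom: str | None = None
    dest_pos: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "translocation"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("rearrangement interval must satisfy 0 <= start < end")
        if self.kind == "translocation" and (self.dest_chrom is None or self.dest_pos is None):
            raise ValueError("translocation needs dest_chrom and dest_pos")


@dataclass
class GenomeSimConfig:
    """Layout of the ancestral genome and the events deriving genome B."""

    n_chromosomes: int = 2
    chrom_length: int = 130_000_000
    n_genes: int = 30
    gene_length: int = 20_000
    rearrangements: list[RearrangementEvent] = field(default_factory=list)
    #: gene_id -> (chrom, start, strand); honored before random placement.
    fixed_genes: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    seed: int = 0

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


def _check_events_disjoint(events: Sequence[RearrangementEvent]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append((ev.start, ev.end))
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping rearrangement intervals on {chrom}: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )


def simulate_ortholog_genomes(
    config: GenomeSimConfig,
    genome_ids: tuple[str, str] = ("genomeA", "genomeB"),
) -> tuple[pd.DataFrame, pd.DataFrame, OrthologMap, list[RearrangementEvent]]:
    """Simulate genome A and its rearranged counterpart genome B.

    Gene identity is preserved across genomes; genome B is genome A with the
    configured events applied.  Returns per-genome annotation frames, the
    combined :class:`OrthologMap`, and the realized events.
    """
    _check_events_disjoint(config.rearrangements)
    rng = np.random.default_rng(config.seed)
    ga, gb = genome_ids

    loci_a: dict[str, GeneLocus] = {}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chromosomes}

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in occupied[chrom])

    for gene_id, (chrom, start, strand) in config.fixed_genes.items():
        end = start + config.gene_length
        if chrom not in occupied:
            raise ValueError(f"fixed gene {gene_id!r} on unknown chromosome {chrom!r}")
        if end > config.chrom_length or overlaps(chrom, start, end):
            raise ValueError(f"fixed gene {gene_id!r} out of bounds or overlapping")
        occupied[chrom].append((start, end))
        loci_a[gene_id] = GeneLocus(chrom, start, end, strand)

    n_random = config.n_genes - len(config.fixed_genes)
    if n_random < 0:
        raise ValueError("n_genes smaller than the number of fixed genes")
    for i in range(n_random):
        gene_id = f"g{i + 1:04d}"
        for _ in range(1000):
            chrom = config.chromosomes[int(rng.integers(config.n_chromosomes))]
            start = int(rng.integers(0, config.chrom_length - config.gene_length))
            end = start + config.gene_length
            if not overlaps(chrom, start, end):
                occupied[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                loci_a[gene_id] = GeneLocus(chrom, start, end, strand)
                break
        else:
            raise RuntimeError("could not place genes without overlap; reduce n_genes")

    # derive genome B by applying the events
    loci_b: dict[str, GeneLocus] = dict(loci_a)
    for ev in config.rearrangements:
        if ev.end > config.chrom_length:
            raise ValueError(f"rearrangement interval exceeds chromosome bounds: {ev}")
        inside = {
            g: loc
            for g, loc in loci_b.items()
            if loc.chrom == ev.chrom and loc.start >= ev.start and loc.end <= ev.end
        }
        straddling = [
            g
            for g, loc in loci_b.items()
            if loc.chrom == ev.chrom
            and loc.start < ev.end
            and loc.end > ev.start
            and g not in inside
        ]
        if straddling:
            raise ValueError(
                f"rearrangement {ev.kind} [{ev.start},{ev.end}) splits genes: {straddling}"
            )
        if ev.kind == "inversion":
            for g, loc in inside.items():
                new_start = ev.start + (ev.end - loc.end)
                new_end = ev.start + (ev.end - loc.start)
                flipped = "-" if loc.strand == "+" else "+"
                loci_b[g] = GeneLocus(loc.chrom, new_start, new_end, flipped)
        else:  # translocation
            for g, loc in inside.items():
                new_start = ev.dest_pos + (loc.start - ev.start)
                loci_b[g] = GeneLocus(ev.dest_chrom, new_start, new_start + loc.length, loc.strand)
            moved = set(inside)
            spans = [
                (loc.start, loc.end)
                for g, loc in loci_b.items()
                if loc.chrom == ev.dest_chrom and g not in moved
            ]
            for g in moved:
                loc = loci_b[g]
                if any(loc.start < e and s < loc.end for s, e in spans):
                    raise ValueError(
                        f"translocation destination overlaps existing genes near {g!r}"
                    )

    omap = OrthologMap({g: {ga: loci_a[g], gb: loci_b[g]} for g in loci_a})

    def frame(loci: Mapping[str, GeneLocus], genome: str) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "genome": genome, "chrom": l.chrom, "start": l.start,
             "end": l.end, "strand": l.strand}
            for g, l in sorted(loci.items(), key=lambda kv: (kv[1].chrom, kv[1].start))
        ]
        return pd.DataFrame(rows)

    return frame(loci_a, ga), frame(loci_b, gb), omap, list(config.rearrangements)


def apc_mcc_scenario(
    seed: int = 0,
    genome_ids: tuple[str, str] = ("human_like", "mouse_like"),
) -> tuple[OrthologMap, list[RearrangementEvent], dict[str, str]]:
    """Packaged two-genome fixture with a driver/proximity-passenger gene pair.

    ``DRV1`` and ``PSG1`` sit 180 kb apart (< 200 kb) on chr1 of genome A; an
    inversion in the B lineage relocates ``PSG1`` so the pair ends up ~10.5 Mb
    apart in genome B.  ``CTL1`` is a control gene far from the pair in both
    genomes.  Returns the ortholog map, the realized events, and a role map
    ``{'driver': 'DRV1', 'passenger': 'PSG1', 'control': 'CTL1'}``.
    """
    gene_len = 20_000
    fixed: dict[str, tuple[str, int, str]] = {
        "DRV1": ("chr1", 112_000_000, "+"),
        "PSG1": ("chr1", 112_180_000, "+"),
        "CTL1": ("chr2", 60_000_000, "+"),
    }
    # background genes on a 1-Mb grid; those inside the inversion get reversed
    for i, pos in enumerate(range(113_000_000, 125_000_000, 1_000_000)):
        fixed[f"BG{i + 1:02d}"] = ("chr1", pos, "+" if i % 2 else "-")
    inversion = RearrangementEvent("inversion", "chr1", 112_150_000, 122_550_000)
    config = GenomeSimConfig(
        n_chromosomes=2,
        chrom_length=130_000_000,
        n_genes=len(fixed),
        gene_length=gene_len,
        rearrangements=[inversion],
        fixed_genes=fixed,
        seed=seed,
    )
    _, _, omap, events = simulate_ortholog_genomes(config, genome_ids)
    return omap, events, {"driver": "DRV1", "passenger": "PSG1", "control": "CTL1"}


# ---------------------------------------------------------------------------
# repeat annotation
# ---------------------------------------------------------------------------

def simulate_repeat_annotation(
    intervals: Sequence[tuple[str, int, int]],
    total_density: float,
    alu_density: float,
    seed: int = 0,
    min_repeat_length: int = 100,
    max_repeat_length: int = 500,
) -> pd.DataFrame:
    """Annotate intervals with non-overlapping repeats at target densities.

    Within each interval, repeats are placed so that their union coverage hits
    ``total_density`` exactly (up to one repeat-length granule) and a subset
    labelled ``Alu`` reaches ``alu_density``; the rest are labelled ``L1``.
    Intervals shorter than ``min_repeat_length`` yield no records, with a
    warning.
    """
    if not (0.0 <= total_density <= 1.0 and 0.0 <= alu_density <= 1.0):
        raise ValueError("densities must be in [0, 1]")
    if alu_density > total_density:
        raise ValueError("Alu density cannot exceed total repeat density")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for chrom, start, end in intervals:
        length = end - start
        if total_density == 0.0:
            continue
        if length < min_repeat_length:
            warnings.warn(
                f"interval {chrom}:{start}-{end} shorter than minimum repeat length; "
                "no repeats placed",
                stacklevel=2,
            )
            continue
        target = int(round(total_density * length))
        lengths: list[int] = []
        while sum(lengths) < target:
            lengths.append(int(rng.integers(min_repeat_length, max_repeat_length + 1)))
        lengths[-1] -= sum(lengths) - target
        lengths = [l for l in lengths if l > 0]
        k = len(lengths)
        gap_total = length - target
        if gap_total > 0 and k:
            weights = rng.dirichlet(np.ones(k + 1))
            gaps = np.floor(weights * gap_total).astype(int)
            gaps[-1] += gap_total - gaps.sum()
        else:
            gaps = np.zeros(k + 1, dtype=int)
        # assign Alu family to a random subset reaching the Alu target
        alu_target = int(round(alu_density * length))
        order = rng.permutation(k)
        alu_flags = np.zeros(k, dtype=bool)
        acc = 0
        for idx in order:
            if acc >= alu_target:
                break
            alu_flags[idx] = True
            acc += lengths[idx]
        pos = start
        for i, rep_len in enumerate(lengths):
            pos += int(gaps[i])
            rows.append(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + rep_len,
                    "family": "Alu" if alu_flags[i] else "L1",
                }
            )
            pos += rep_len
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


# ---------------------------------------------------------------------------
# tumor cohorts under the proximity model
# ---------------------------------------------------------------------------

@dataclass
class ProximityModelConfig:
    """Distance-decay mutagenesis model.

    A non-driver gene acquires a truncating lesion in a tumor with probability
    ``background_rate + sum_over_drivers amplitude * exp(-d / decay_length)``,
    where d is the start-to-start distance to the driver in that genome
    (unlinked genes contribute nothing).  Driver genes are mutated with
    probability ``driver_rate``.
    """

    background_rate: float = 0.01
    amplitude: float = 0.5
    decay_length: float = 500_000.0
    driver_rate: float = 0.9
    driver_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("background_rate", "amplitude", "driver_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if self.background_rate + self.amplitude > 1.0:
            raise ValueError("background_rate + amplitude must not exceed 1")


def proximity_rate(
    gene: str,
    genome: str,
    omap: OrthologMap,
    config: ProximityModelConfig,
) -> float:
    """Per-tumor truncating-lesion probability for one gene in one genome."""
    if gene in config.driver_genes:
        return config.driver_rate
    rate = config.background_rate
    for driver in config.driver_genes:
        d = gene_pair_distance(gene, driver, genome, omap)
        if d is not UNLINKED and math.isfinite(d):
            rate += config.amplitude * math.exp(-d / config.decay_length)
    return min(rate, 1.0)


def simulate_cds_sequences(
    genes: Iterable[str],
    cds_length: int = 300,
    seed: int = 0,
) -> dict[str, str]:
    """Random reference CDS per gene: in-frame, no internal stop codons."""
    if cds_length % 3:
        raise ValueError("cds_length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOP_CODONS]
    out: dict[str, str] = {}
    for gene in genes:
        idx = rng.integers(0, len(codons), size=cds_length // 3)
        out[gene] = "".join(codons[i] for i in idx)
    return out


@functools.lru_cache(maxsize=256)
def _nonsense_candidates(cds: str) -> list[tuple[int, str, str]]:
    """(1-based CDS pos, ref, alt) substitutions that create a stop codon."""
    out = []
    for c in range(len(cds) // 3):
        codon = cds[3 * c : 3 * c + 3]
        for off in range(3):
            for alt in _BASES:
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 1 :]
                if mutated in _STOP_CODONS:
                    out.append((3 * c + off + 1, codon[off], alt))
    return out


def _draw_truncating_lesion(cds: str, rng: np.random.Generator) -> tuple[int, str, str, str]:
    """Draw (cds_pos, ref, alt, kind): 50/50 nonsense substitution vs 1-2 bp indel."""
    if rng.random() < 0.5:
        candidates = _nonsense_candidates(cds)
        if candidates:
            pos, ref, alt = candidates[int(rng.integers(len(candidates)))]
            return pos, ref, alt, "substitution"
    size = int(rng.integers(1, 3))
    if rng.random() < 0.5:  # insertion before position pos
        pos = int(rng.integers(2, len(cds) + 1))
        ins = "".join(_BASES[int(rng.integers(4))] for _ in range(size))
        return pos, "-", ins, "insertion"
    pos = int(rng.integers(2, len(cds) - size + 1))
    return pos, cds[pos - 1 : pos - 1 + size], "-", "deletion"


def simulate_tumor_cohort(
    omap: OrthologMap,
    genomes: Sequence[str],
    config: ProximityModelConfig,
    n_tumors: int,
    seed: int = 0,
    cds_sequences: Mapping[str, str] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-genome truth tables of injected truncating lesions.

    Returns a frame with columns ``genome, tumor, gene, cds_pos, ref, alt,
    kind, truncating`` recording every injected lesion.  ``genes`` restricts
    the assayed panel (default: all genes in the map).  ``cds_sequences``
    supplies reference CDSs; generated deterministically from ``seed`` when
    omitted.
    """
    panel = list(genes) if genes is not None else omap.genes
    for driver in config.driver_genes:
        for genome in genomes:
            if not omap.has(driver, genome):
                raise ValueError(f"driver gene {driver!r} missing from genome {genome!r}")
    if cds_sequences is None:
        cds_sequences = simulate_cds_sequences(panel, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows: list[dict] = []
    for genome in genomes:
        for gene in panel:
            if not omap.has(gene, genome):
                continue
            rate = proximity_rate(gene, genome, omap, config)
            cds = cds_sequences[gene]
            for t in range(n_tumors):
                if rng.random() < rate:
                    pos, ref, alt, kind = _draw_truncating_lesion(cds, rng)
                    rows.append(
                        {
                            "genome": genome,
                            "tumor": f"{genome}_T{t + 1:03d}",
                            "gene": gene,
                            "cds_pos": pos,
                            "ref": ref,
                            "alt": alt,
                            "kind": kind,
                            "truncating": True,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["genome", "tumor", "gene", "cds_pos", "ref", "alt", "kind", "truncating"]
    )


def apply_variants(cds: str, variants: Iterable[tuple[int, str, str, str]]) -> str:
    """Apply (cds_pos, ref, alt, kind) lesions to a reference CDS.

    Insertions are placed so the first inserted base occupies ``cds_pos``;
    deletions remove ``len(ref)`` bases starting at ``cds_pos``.  Variants are
    applied right-to-left so earlier coordinates stay valid.
    """
    seq = cds
    for pos, ref, alt, kind in sorted(variants, key=lambda v: -v[0]):
        i = pos - 1
        if kind == "substitution":
            if seq[i] != ref:
                raise ValueError(f"ref mismatch at CDS {pos}: {seq[i]!r} != {ref!r}")
            seq = seq[:i] + alt + seq[i + 1 :]
        elif kind == "insertion":
            seq = seq[:i] + alt + seq[i:]
        elif kind == "deletion":
            if seq[i : i + len(ref)] != ref:
                raise ValueError(f"ref mismatch for deletion at CDS {pos}")
            seq = seq[:i] + seq[i + len(ref) :]
        else:
            raise ValueError(f"unknown variant kind {kind!r}")
    return seq


# ---------------------------------------------------------------------------
# trace reads
# ---------------------------------------------------------------------------

@dataclass
class TraceSimConfig:
    """Sanger-like read simulation: low-quality ends, high-quality interior.

    Per-base miscalls are injected with probability ``10**(-Q/10)`` at the
    base's assigned quality Q.  ``quality_profile`` (per-position phreds)
    overrides the end/interior parametrisation when given.
    """

    quality_interior: int = 45
    quality_end: int = 8
    end_length: int = 15
    quality_profile: np.ndarray | None = None
    max_read_length: int | None = None

    def profile(self, n: int) -> np.ndarray:
        if self.quality_profile is not None:
            prof = np.asarray(self.quality_profile, dtype=int)
            if len(prof) < n:
                prof = np.concatenate([prof, np.full(n - len(prof), prof[-1] if len(prof) else 0)])
            return prof[:n]
        prof = np.full(n, self.quality_interior, dtype=int)
        e = min(self.end_length, n)
        prof[:e] = self.quality_end
        prof[n - e :] = self.quality_end
        return prof

    def __post_init__(self) -> None:
        if self.quality_profile is not None and (np.asarray(self.quality_profile) < 0).any():
            raise ValueError("qualities must be >= 0")


def _inject_errors(seq: str, quals: np.ndarray, rng: np.random.Generator) -> str:
    p_err = 10.0 ** (-quals / 10.0)
    hits = rng.random(len(seq)) < p_err
    if not hits.any():
        return seq
    chars = list(seq)
    for i in np.nonzero(hits)[0]:
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def simulate_trace_pair(
    truth_seq: str,
    config: TraceSimConfig,
    seed: int | np.random.Generator = 0,
    read_id: str = "amplicon",
) -> tuple[TraceRead, TraceRead]:
    """Forward and reverse reads of one amplicon with phred-calibrated errors.

    The forward read covers the amplicon from its 5' end, the reverse read is
    the reverse complement from the 3' end, each with its own quality profile
    and independent errors.  Degenerate inputs (empty truth) yield flagged
    empty reads rather than errors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(truth_seq)
    read_len = n if config.max_read_length is None else min(n, config.max_read_length)
    if n == 0:
        empty = TraceRead(f"{read_id}.failed", "forward", "", np.zeros(0, dtype=int))
        return empty, TraceRead(f"{read_id}.failed", "reverse", "", np.zeros(0, dtype=int))
    fwd_truth = truth_seq[:read_len]
    rev_truth = revcomp(truth_seq[n - read_len :])
    q_fwd = config.profile(read_len)
    q_rev = config.profile(read_len)
    fwd = TraceRead(f"{read_id}.f", "forward", _inject_errors(fwd_truth, q_fwd, rng), q_fwd)
    rev = TraceRead(f"{read_id}.r", "reverse", _inject_errors(rev_truth, q_rev, rng), q_rev)
    return fwd, rev


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    genes: Sequence[str],
    n_pairs: int,
    effects: Mapping[str, float],
    replicate_sd: float = 0.15,
    seed: int = 0,
    n_replicates: int = 3,
    sample_shift_sd: float = 0.0,
    baseline: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Triplicate Ct measurements for paired tumor/normal samples.

    ``effects[gene]`` is the tumor shift in Ct units (positive = fewer
    templates in tumor); genes absent from ``effects`` (e.g. reference genes)
    get effect 0.  ``sample_shift_sd`` adds a per-sample global additive shift
    shared by all genes of that sample, which ΔCt normalization removes.
    """
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if baseline is None:
        baseline = {g: float(rng.uniform(18.0, 26.0)) for g in genes}
    rows = []
    for p in range(1, n_pairs + 1):
        for tissue in ("normal", "tumor"):
            shift = float(rng.normal(0.0, sample_shift_sd)) if sample_shift_sd > 0 else 0.0
            for gene in genes:
                mu = baseline[gene] + shift
                if tissue == "tumor":
                    mu += effects.get(gene, 0.0)
                reps = mu + rng.normal(0.0, replicate_sd, size=n_replicates) if replicate_sd > 0 else np.full(n_replicates, mu)
                row = {"pair_id": f"P{p:02d}", "tissue": tissue, "gene": gene}
                row.update({f"ct{i + 1}": float(reps[i]) for i in range(n_replicates)})
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aCGH profiles
# ---------------------------------------------------------------------------

@dataclass
class CghSimConfig:
    """Single-chromosome aCGH profile with a target altered-genome fraction."""

    genome_length: int = 100_000_000
    probe_spacing: int = 5_000
    altered_fraction: float = 0.04
    segment_length_range: tuple[int, int] = (500_000, 2_000_000)
    gain_log2: float = 0.8
    loss_log2: float = -0.8
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.altered_fraction <= 1.0):
            raise ValueError("altered_fraction must be in [0, 1]")
        if self.probe_spacing <= 0 or self.genome_length <= 0:
            raise ValueError("genome_length and probe_spacing must be positive")
        if self.altered_fraction > 0 and self.segment_length_range[1] < self.probe_spacing:
            raise ValueError("max segment length shorter than probe spacing")


def simulate_cgh_profile(config: CghSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate probe log2 ratios plus the truth altered segments.

    Probes sit every ``probe_spacing`` bp (count = floor(genome_length /
    spacing)).  Altered segments of random length are placed without overlap
    (kept one segment-length apart) until their summed length matches
    ``altered_fraction * genome_length`` exactly; gains and losses alternate.
    """
    rng = np.random.default_rng(config.seed)
    n_probes = config.genome_length // config.probe_spacing
    positions = np.arange(n_probes, dtype=int) * config.probe_spacing
    log2 = rng.normal(0.0, config.noise_sd, size=n_probes)

    truth_rows: list[dict] = []
    target = int(round(config.altered_fraction * config.genome_length))
    if target > 0:
        lo, hi = config.segment_length_range
        lengths: list[int] = []
        while sum(lengths) < target:
            lengths.append(int(rng.integers(lo, hi + 1)))
        lengths[-1] -= sum(lengths) - target
        lengths = [l for l in lengths if l >= config.probe_spacing]
        placed: list[tuple[int, int]] = []
        margin = hi  # keep segments well separated so they are distinct events
        for i, seg_len in enumerate(lengths):
            for _ in range(1000):
                start = int(rng.integers(0, config.genome_length - seg_len))
                end = start + seg_len
                if all(start - margin >= e or end + margin <= s for s, e in placed):
                    placed.append((start, end))
                    break
            else:
                raise RuntimeError("could not place altered segments without overlap")
            mean = config.gain_log2 if i % 2 == 0 else config.loss_log2
            mask = (positions >= start) & (positions < end)
            log2[mask] += mean
            truth_rows.append(
                {"chrom": "chr1", "start": start, "end": end, "log2_mean": mean,
                 "state": "gain" if mean > 0 else "loss"}
            )

    profile = pd.DataFrame({"chrom": "chr1", "pos": positions, "log2_ratio": log2})
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "log2_mean", "state"])
    return profile, truth
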