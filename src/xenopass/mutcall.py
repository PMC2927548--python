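"""Quality-aware tumor/normal mutation calling from paired Sanger-style reads.

The chain mirrors a classic exon-resequencing pipeline: per-read quality
trimming, forward/reverse consensus assembly, global alignment of the tumor
consensus against the matched normal consensus, quality-filtered difference
calling, and codon-level effect classification.  Truncating lesions (nonsense
substitutions and frameshift indels) are the signal of interest; missense and
noncoding changes are recorded but excluded from truncating summaries.

Phred convention: a base with quality Q has error probability 10**(-Q/10),
so Q=20 means at most 1% miscalls.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class TraceRead:
    """One sequencing read: bases plus per-base phred qualities."""

    id: str
    orientation: str  # 'forward' | 'reverse'
    bases: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.qualities)} qualities"
            )
        if (self.qualities < 0).any():
            raise ValueError(f"read {self.id!r}: negative quality score")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"read {self.id!r}: bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.bases)

    def to_reference_orientation(self) -> "TraceRead":
        """Reverse reads are complemented back to the reference strand."""
        if self.orientation == "forward":
            return self
        return TraceRead(self.id, "forward", revcomp(self.bases), self.qualities[::-1].copy())


@dataclass(frozen=True)
class ExonModel:
    """Coding context of one exon; cds_offset is the 1-based CDS position of
    the exon's first coding base."""

    gene: str
    ordinal: int
    chrom: str
    start: int
    end: int
    strand: str
    coding: bool
    cds_offset: int = 1

    def __post_init__(self) -> None:
        if self.coding and self.cds_offset < 1:
            raise ValueError("coding exons need cds_offset >= 1")


@dataclass
class ConsensusSequence:
    bases: str
    qualities: np.ndarray
    n_high_quality: int
    success: bool
    hq_threshold: int = 20
    #: 0-based offset of the first consensus base in reference-exon
    #: coordinates (end trimming removes the read edges, so the consensus
    #: usually starts a few bases into the exon).
    ref_start: int = 0


class MutationEffect(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    NONCODING = "noncoding"


TRUNCATING = frozenset({MutationEffect.NONSENSE, MutationEffect.FRAMESHIFT})


@dataclass(frozen=True)
class VariantCall:
    gene: str
    cds_pos: int  # 1-based; for insertions, coordinate the first inserted base would take
    ref: str
    alt: str
    kind: str  # 'substitution' | 'insertion' | 'deletion'
    min_qual: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


def phred_error(q: float) -> float:
    """Error probability implied by a phred quality score: 10**(-q/10)."""
    if q < 0:
        raise ValueError(f"phred quality must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def trim_read(read: TraceRead, window: int = 10, qmin: float = 20.0) -> tuple[int, int]:
    """Longest quality-passing interval of a read (0-based half-open).

    A substring passes when every sliding window of length ``min(window,
    len(substring))`` inside it has mean quality >= ``qmin``; the leftmost
    longest passing substring is retained.  An empty interval ``(0, 0)``
    means the read failed trimming entirely.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = read.qualities.astype(float)
    n = len(q)
    if n == 0:
        return (0, 0)
    if n >= window:
        means = np.convolve(q, np.ones(window) / window, mode="valid")
        ok = means >= qmin
        # longest run of consecutive passing windows -> substring run+window-1 long
        best_len, best_start = 0, 0
        run, run_start = 0, 0
        for i, flag in enumerate(ok):
            if flag:
                if run == 0:
                    run_start = i
                run += 1
                cand = run + window - 1
                if cand > best_len:
                    best_len, best_start = cand, run_start
            else:
                run = 0
        if best_len:
            return (best_start, best_start + best_len)
    # no full window passes (or read shorter than window): the best candidate
    # is a substring shorter than the window, which passes iff its own mean
    # quality is >= qmin.
    for length in range(min(window - 1, n), 0, -1):
        means = np.convolve(q, np.ones(length) / length, mode="valid")
        hits = np.nonzero(means >= qmin)[0]
        if hits.size:
            start = int(hits[0])
            return (start, start + length)
    return (0, 0)


def apply_trim(read: TraceRead, window: int = 10, qmin: float = 20.0) -> TraceRead:
    start, end = trim_read(read, window, qmin)
    return TraceRead(read.id, read.orientation, read.bases[start:end], read.qualities[start:end].copy())


@dataclass(frozen=True)
class Alignment:
    """Gapped global alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython convention: open score applies to the first gapped position,
    # so a length-L gap costs gap_open + (L-1)*gap_extend.
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_global(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> Alignment:
    """Optimal global alignment with affine gaps (Needleman-Wunsch/Gotoh).

    A length-L gap costs ``gap_open + (L-1)*gap_extend``.  Ties are broken
    deterministically by taking the aligner's first optimal traceback.
    """
    if not seq_a or not seq_b:
        raise ValueError("align_global requires non-empty sequences")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    return Alignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=float(aln.score))


def assemble_exon_consensus(
    forward: TraceRead | None,
    reverse: TraceRead | None,
    reference: str | None = None,
    min_hq_bases: int = 100,
    hq_threshold: int = 20,
    trim: bool = True,
    trim_window: int = 10,
    trim_qmin: float = 20.0,
) -> ConsensusSequence:
    """Merge forward and reverse reads of one amplicon into an exon consensus.

    Reads are quality-trimmed, the reverse read is complemented back to the
    reference strand, and the two are globally aligned to each other.  Per
    column: agreeing bases keep the higher quality; disagreeing bases take the
    higher-quality call; exact quality ties yield ``N`` with quality 0 (never
    a variant).  Columns covered by a single read take that read's base.  The
    consensus *succeeds* when it retains at least ``min_hq_bases`` bases with
    quality >= ``hq_threshold``.  When ``reference`` (the exon's reference
    sequence) is given, the merged consensus is anchored to it and its
    ``ref_start`` offset recorded, so downstream variant positions are in
    exon/CDS coordinates even after end trimming.
    """
    reads = []
    for read in (forward, reverse):
        if read is None:
            continue
        oriented = read.to_reference_orientation()
        if trim:
            oriented = apply_trim(oriented, trim_window, trim_qmin)
        if len(oriented):
            reads.append(oriented)
    if not reads:
        return ConsensusSequence("", np.zeros(0, dtype=int), 0, False, hq_threshold)
    if len(reads) == 1:
        r = reads[0]
        n_hq = int((r.qualities >= hq_threshold).sum())
        return ConsensusSequence(
            r.bases, r.qualities.copy(), n_hq, n_hq >= min_hq_bases, hq_threshold,
            ref_start=_anchor_offset(reference, r.bases),
        )

    r1, r2 = reads
    aln = align_global(r1.bases, r2.bases)
    bases: list[str] = []
    quals: list[int] = []
    i = j = 0
    for c1, c2 in zip(aln.aligned_a, aln.aligned_b):
        if c1 != "-" and c2 != "-":
            q1, q2 = int(r1.qualities[i]), int(r2.qualities[j])
            if c1 == c2:
                bases.append(c1)
                quals.append(max(q1, q2))
            elif q1 > q2:
                bases.append(c1)
                quals.append(q1)
            elif q2 > q1:
                bases.append(c2)
                quals.append(q2)
            else:
                bases.append("N")
                quals.append(0)
            i += 1
            j += 1
        elif c1 != "-":
            bases.append(c1)
            quals.append(int(r1.qualities[i]))
            i += 1
        else:
            bases.append(c2)
            quals.append(int(r2.qualities[j]))
            j += 1
    qual_arr = np.asarray(quals, dtype=int)
    n_hq = int((qual_arr >= hq_threshold).sum())
    merged = "".join(bases)
    return ConsensusSequence(
        merged, qual_arr, n_hq, n_hq >= min_hq_bases, hq_threshold,
        ref_start=_anchor_offset(reference, merged),
    )


def _anchor_offset(reference: str | None, consensus: str) -> int:
    """Reference-coordinate offset of the consensus start (0 without a reference)."""
    if reference is None or not consensus:
        return 0
    aln = align_global(reference, consensus)
    ref_idx = 0
    for cr, cc in zip(aln.aligned_a, aln.aligned_b):
        if cc != "-":
            return ref_idx
        if cr != "-":
            ref_idx += 1
    return 0


def call_variants(
    tumor: ConsensusSequence,
    normal: ConsensusSequence,
    exon: ExonModel,
    qmin: int = 20,
) -> list[VariantCall]:
    """Quality-filtered differences between tumor and normal exon consensi.

    Substitutions are emitted when both the tumor and normal base have
    quality >= ``qmin``.  Indels additionally require every inserted/deleted
    base *and* one flanking anchor column (both sequences) to pass ``qmin``.
    ``N`` bases (consensus ties) never produce calls.  Positions are reported
    in 1-based CDS coordinates for coding exons (insertions take the CDS
    coordinate their first base would occupy), using the normal consensus's
    reference anchor (``ref_start``) so trimmed ends do not shift coordinates;
    noncoding exons use the same bookkeeping relative to the exon start.
    """
    if not tumor.bases or not normal.bases:
        return []
    base_pos = exon.cds_offset + normal.ref_start
    aln = align_global(tumor.bases, normal.bases)
    cols = list(zip(aln.aligned_a, aln.aligned_b))
    # precompute per-column (tumor_idx, normal_idx, t_qual, n_qual)
    meta: list[tuple[int | None, int | None, int, int]] = []
    ti = ni = 0
    for ct, cn in cols:
        t_idx = ti if ct != "-" else None
        n_idx = ni if cn != "-" else None
        tq = int(tumor.qualities[ti]) if ct != "-" else -1
        nq = int(normal.qualities[ni]) if cn != "-" else -1
        meta.append((t_idx, n_idx, tq, nq))
        if ct != "-":
            ti += 1
        if cn != "-":
            ni += 1

    def anchor_ok(col: int) -> bool:
        """Nearest column to the left where both sequences have a base."""
        for k in range(col - 1, -1, -1):
            ct, cn = cols[k]
            if ct != "-" and cn != "-":
                return (
                    ct != "N"
                    and cn != "N"
                    and meta[k][2] >= qmin
                    and meta[k][3] >= qmin
                )
        return False  # indel at the very start has no anchor

    calls: list[VariantCall] = []
    k = 0
    n_cols = len(cols)
    while k < n_cols:
        ct, cn = cols[k]
        if ct != "-" and cn != "-":
            if ct != cn and ct != "N" and cn != "N":
                tq, nq = meta[k][2], meta[k][3]
                if min(tq, nq) >= qmin:
                    pos = base_pos + meta[k][1]
                    calls.append(VariantCall(exon.gene, pos, cn, ct, "substitution", min(tq, nq)))
            k += 1
            continue
        # gap run: insertion (gaps in normal) or deletion (gaps in tumor)
        run_start = k
        gap_in_normal = cn == "-"
        while k < n_cols and (cols[k][1] == "-" if gap_in_normal else cols[k][0] == "-"):
            k += 1
        run = range(run_start, k)
        if gap_in_normal:
            inserted = "".join(cols[c][0] for c in run)
            quals = [meta[c][2] for c in run]
            if "N" not in inserted and all(q >= qmin for q in quals) and anchor_ok(run_start):
                nxt_n = next((meta[c][1] for c in range(k, n_cols) if meta[c][1] is not None), ni)
                pos = base_pos + nxt_n
                calls.append(VariantCall(exon.gene, pos, "-", inserted, "insertion", min(quals)))
        else:
            deleted = "".join(cols[c][1] for c in run)
            quals = [meta[c][3] for c in run]
            if "N" not in deleted and all(q >= qmin for q in quals) and anchor_ok(run_start):
                pos = base_pos + meta[run_start][1]
                calls.append(VariantCall(exon.gene, pos, deleted, "-", "deletion", min(quals)))
    return calls


def map_to_codon(cds_pos: int) -> tuple[int, int]:
    """1-based CDS position -> (codon index, offset within codon), both 1-based.

    Satisfies 3*(codon-1) + offset == cds_pos.
    """
    if cds_pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {cds_pos}")
    return (cds_pos + 2) // 3, (cds_pos - 1) % 3 + 1


def classify_effect(variant: VariantCall, exon: ExonModel, cds_seq: str | None = None) -> MutationEffect:
    """Codon-level consequence of one variant.

    Coding substitutions are translated (ref vs alt codon, standard table);
    coding indels are frameshift iff their length is not a multiple of 3;
    anything in a noncoding exon is ``noncoding``.  ``cds_seq`` (the reference
    CDS) is required to classify coding substitutions.
    """
    if not exon.coding:
        return MutationEffect.NONCODING
    if variant.kind in ("insertion", "deletion"):
        length = len(variant.alt if variant.kind == "insertion" else variant.ref)
        return MutationEffect.FRAMESHIFT if length % 3 else MutationEffect.INFRAME_INDEL
    if cds_seq is None:
        raise ValueError("classifying a coding substitution requires the reference CDS")
    if not (1 <= variant.cds_pos <= len(cds_seq)):
        raise ValueError(
            f"variant at CDS position {variant.cds_pos} lies outside the {len(cds_seq)} bp CDS"
        )
    codon_idx, offset = map_to_codon(variant.cds_pos)
    start = 3 * (codon_idx - 1)
    ref_codon = cds_seq[start : start + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"incomplete codon at CDS position {variant.cds_pos}")
    if ref_codon[offset - 1] != variant.ref:
        warnings.warn(
            f"reference CDS has {ref_codon[offset - 1]!r} at position {variant.cds_pos}, "
            f"variant says {variant.ref!r}",
            stacklevel=2,
        )
    alt_codon = ref_codon[: offset - 1] + variant.alt + ref_codon[offset:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        return MutationEffect.NONSENSE
    if alt_aa == ref_aa:
        return MutationEffect.SYNONYMOUS
    return MutationEffect.MISSENSE


@dataclass
class CohortSummary:
    """Per-gene truncating prevalence plus sequencing bookkeeping."""

    truncating_counts: dict[str, int]
    samples_per_gene: dict[str, int]
    attempts: int
    successes: int
    success_rate_pct: int | None
    rate_undefined: bool

    def prevalence(self, gene: str) -> tuple[int, int]:
        """(k tumors with a truncating lesion, n tumors assayed) for a gene."""
        return self.truncating_counts.get(gene, 0), self.samples_per_gene.get(gene, 0)


def summarize_cohort(
    calls_by_sample: Mapping[str, Sequence[tuple[VariantCall, MutationEffect]]],
    read_success_flags: Iterable[bool],
    genes: Iterable[str] | None = None,
) -> CohortSummary:
    """Cohort-level rollup: truncating counts per gene and the sequencing
    success rate (successes/attempts, reported to the nearest integer percent).

    ``calls_by_sample`` maps each tumor sample to its (variant, effect) pairs;
    a sample counts once per gene no matter how many truncating lesions it
    carries.  ``genes`` fixes the set of assayed genes (so genes with zero
    calls still report n).
    """
    flags = list(read_success_flags)
    attempts = len(flags)
    successes = sum(bool(f) for f in flags)
    if attempts == 0:
        rate, undefined = None, True
    else:
        rate, undefined = round(100 * successes / attempts), False

    gene_set = set(genes) if genes is not None else {
        v.gene for calls in calls_by_sample.values() for v, _ in calls
    }
    trunc: dict[str, int] = {g: 0 for g in gene_set}
    per_gene_n: dict[str, int] = {g: len(calls_by_sample) for g in gene_set}
    for sample, calls in calls_by_sample.items():
        hit = {v.gene for v, eff in calls if eff in TRUNCATING}
        for g in hit:
            trunc[g] = trunc.get(g, 0) + 1
            per_gene_n.setdefault(g, len(calls_by_sample))
    return CohortSummary(trunc, per_gene_n, attempts, successes, rate, undefined)


def read_is_successful(
    read: TraceRead,
    min_hq_bases: int = 100,
    hq_threshold: int = 20,
    trim_window: int = 10,
    trim_qmin: float = 20.0,
) -> bool:
    """Attempt/success bookkeeping: a read succeeds when, after end trimming,
    it retains at least ``min_hq_bases`` bases of quality >= ``hq_threshold``."""
    trimmed = apply_trim(read, trim_window, trim_qmin)
    return int((trimmed.qualities >= hq_threshold).sum()) >= min_hq_bases
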