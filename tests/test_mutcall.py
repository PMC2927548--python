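"""Mutation-calling chain: phred model, trimming vs a brute-force oracle,
consensus rules, alignment optimality vs exhaustive enumeration, quality-
filtered variant calling, codon mapping and effect classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenopass import mutcall as mc
from xenopass import simcohort as sim


def _read(bases, quals, orientation="forward", rid="r1"):
    return mc.TraceRead(rid, orientation, bases, np.asarray(quals, int))


# ---------------------------------------------------------------------------
# phred model
# ---------------------------------------------------------------------------

def test_phred_error_reference_values():
    assert mc.phred_error(20) == pytest.approx(0.01)
    assert mc.phred_error(0) == 1.0
    assert mc.phred_error(30) == pytest.approx(0.001)


def test_phred_error_strictly_decreasing_and_rejects_negative():
    qs = np.arange(0, 60)
    errs = [mc.phred_error(q) for q in qs]
    assert all(a > b for a, b in zip(errs, errs[1:]))
    with pytest.raises(ValueError):
        mc.phred_error(-1)


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def _trim_oracle(quals, window, qmin):
    """O(n^2) oracle: leftmost longest substring in which every window of
    length min(window, substring length) has mean quality >= qmin."""
    n = len(quals)
    prefix = np.concatenate([[0], np.cumsum(quals)])

    def passes(s, e):
        w = min(window, e - s)
        return all(
            (prefix[i + w] - prefix[i]) / w >= qmin for i in range(s, e - w + 1)
        )

    best = (0, 0)
    for s in range(n):
        for e in range(s + 1, n + 1):
            if passes(s, e) and (e - s) > (best[1] - best[0]):
                best = (s, e)
    return best


def test_trim_uniform_high_quality_keeps_full_read():
    read = _read("A" * 50, [40] * 50)
    assert mc.trim_read(read, window=10, qmin=20) == (0, 50)


def test_trim_uniform_low_quality_empties_read():
    read = _read("A" * 50, [5] * 50)
    assert mc.trim_read(read, window=10, qmin=20) == (0, 0)


def test_trim_low_quality_ends_matches_oracle():
    quals = [5] * 20 + [40] * 60 + [5] * 20
    read = _read("A" * 100, quals)
    assert mc.trim_read(read, window=10, qmin=20) == _trim_oracle(quals, 10, 20)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=1, max_size=40), st.integers(1, 12))
def test_trim_matches_brute_force_oracle(quals, window):
    read = _read("A" * len(quals), quals)
    assert mc.trim_read(read, window=window, qmin=20) == _trim_oracle(quals, window, 20)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _score_alignment(a, b, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    score = 0.0
    prev = None
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            op = "ga" if cb == "-" else "gb"
            score += gap_extend if prev == op else gap_open
            prev = op
        else:
            score += match if ca == cb else mismatch
            prev = "m"
    return score


def _enumerate_alignments(a, b):
    """Exhaustive enumeration of all global alignments (oracle for short seqs)."""
    best = -np.inf

    def walk(i, j, cols_a, cols_b):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, _score_alignment(cols_a, cols_b))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, cols_a + a[i], cols_b + b[j])
        if i < len(a):
            walk(i + 1, j, cols_a + a[i], cols_b + "-")
        if j < len(b):
            walk(i, j + 1, cols_a + "-", cols_b + b[j])

    walk(0, 0, "", "")
    return best


def test_align_identical_sequences_all_match():
    aln = mc.align_global("ACGTACGT", "ACGTACGT")
    assert aln.aligned_a == aln.aligned_b == "ACGTACGT"
    assert aln.score == 8.0


def test_align_single_gap_example():
    aln = mc.align_global("ACGT", "AGT")
    assert aln.score == _enumerate_alignments("ACGT", "AGT") == -2.0
    assert (aln.aligned_a.count("-") + aln.aligned_b.count("-")) == 1


def test_align_two_bp_insertion_single_gap():
    normal = "ACGTACGTACGTACGT"
    tumor = normal[:8] + "GG" + normal[8:]
    aln = mc.align_global(tumor, normal)
    # exactly one gap run of length 2 in the normal row
    gaps = [len(list(g)) for k, g in itertools.groupby(aln.aligned_b, key=lambda c: c == "-") if k]
    assert gaps == [2]


def test_align_score_matches_enumeration_on_random_pairs(rng):
    bases = "ACGT"
    for _ in range(8):
        a = "".join(rng.choice(list(bases), size=rng.integers(1, 9)))
        b = "".join(rng.choice(list(bases), size=rng.integers(1, 9)))
        assert mc.align_global(a, b).score == pytest.approx(_enumerate_alignments(a, b))


# ---------------------------------------------------------------------------
# consensus assembly
# ---------------------------------------------------------------------------

def _pair_from(seq_f, quals_f, seq_r_refstrand, quals_r_refstrand):
    fwd = _read(seq_f, quals_f, "forward", "p.f")
    rev = _read(mc.revcomp(seq_r_refstrand), list(quals_r_refstrand)[::-1], "reverse", "p.r")
    return fwd, rev


def test_consensus_identical_reads_elementwise_max_quality():
    seq = "ACGT" * 30
    fwd, rev = _pair_from(seq, [30] * 120, seq, [45] * 120)
    cons = mc.assemble_exon_consensus(fwd, rev, trim=False)
    assert cons.bases == seq
    assert (cons.qualities == 45).all()
    assert cons.success  # 120 bases >= 100 at Q >= 20


def test_consensus_disagreement_higher_quality_wins():
    seq_t = "ACGTT" + "ACGT" * 30
    seq_a = "ACGTA" + "ACGT" * 30
    q_t = [46] * len(seq_t)
    q_a = [30] * len(seq_a)
    fwd, rev = _pair_from(seq_t, q_t, seq_a, q_a)
    cons = mc.assemble_exon_consensus(fwd, rev, trim=False)
    assert cons.bases[4] == "T"
    assert cons.qualities[4] == 46


def test_consensus_quality_tie_yields_N():
    seq_t = "ACGTT" + "ACGT" * 30
    seq_a = "ACGTA" + "ACGT" * 30
    fwd, rev = _pair_from(seq_t, [40] * len(seq_t), seq_a, [40] * len(seq_a))
    cons = mc.assemble_exon_consensus(fwd, rev, trim=False)
    assert cons.bases[4] == "N"
    assert cons.qualities[4] == 0


@pytest.mark.parametrize("n_bases,expect", [(99, False), (100, True)])
def test_consensus_success_needs_100_high_quality_bases(n_bases, expect):
    read = _read("A" * n_bases, [40] * n_bases)
    cons = mc.assemble_exon_consensus(read, None, trim=False)
    assert cons.success is expect


def test_consensus_zero_usable_reads_fails():
    cons = mc.assemble_exon_consensus(None, None)
    assert not cons.success and cons.bases == ""


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

EXON = mc.ExonModel("GENE", 1, "cds", 0, 300, "+", coding=True, cds_offset=1)


def _consensus(bases, quals, ref_start=0):
    q = np.asarray(quals, int)
    return mc.ConsensusSequence(bases, q, int((q >= 20).sum()), True, ref_start=ref_start)


def test_identical_consensi_no_calls():
    seq = "ACGT" * 40
    assert mc.call_variants(_consensus(seq, [40] * 160), _consensus(seq, [40] * 160), EXON) == []


def test_substitution_called_when_both_bases_pass_qmin():
    normal = "ACGTACGTACGT" * 10
    tumor = normal[:50] + "A" + normal[51:]
    assert normal[50] != "A"
    calls = mc.call_variants(_consensus(tumor, [46] * 120), _consensus(normal, [35] * 120), EXON)
    assert len(calls) == 1
    v = calls[0]
    assert (v.cds_pos, v.ref, v.alt, v.kind, v.min_qual) == (51, normal[50], "A", "substitution", 35)


def test_substitution_suppressed_below_qmin():
    normal = "ACGTACGTACGT" * 10
    tumor = normal[:50] + "A" + normal[51:]
    q_tumor = [46] * 120
    q_tumor[50] = 15
    calls = mc.call_variants(_consensus(tumor, q_tumor), _consensus(normal, [35] * 120), EXON)
    assert calls == []


def test_insertion_called_with_anchor_quality_rule():
    normal = "ACGTACGTACGTACGTACGTACGTACGT" * 5
    tumor = normal[:60] + "GG" + normal[60:]
    calls = mc.call_variants(_consensus(tumor, [40] * len(tumor)), _consensus(normal, [40] * len(normal)), EXON)
    assert len(calls) == 1
    v = calls[0]
    assert (v.kind, v.alt, v.cds_pos) == ("insertion", "GG", 61)
    # low-quality inserted base suppresses the call
    q_bad = [40] * len(tumor)
    q_bad[60] = 10
    assert mc.call_variants(_consensus(tumor, q_bad), _consensus(normal, [40] * len(normal)), EXON) == []


def test_deletion_called_and_positions_respect_ref_anchor():
    normal = "ACGTAACCGGTTACGT" * 8
    tumor = normal[:40] + normal[43:]
    calls = mc.call_variants(
        _consensus(tumor, [40] * len(tumor), ref_start=10),
        _consensus(normal, [40] * len(normal), ref_start=10),
        EXON,
    )
    assert len(calls) == 1
    v = calls[0]
    assert v.kind == "deletion" and len(v.ref) == 3
    assert v.cds_pos == 41 + 10  # shifted by the trimmed prefix


def test_consensus_N_never_yields_calls():
    normal = "ACGT" * 30
    tumor = normal[:50] + "N" + normal[51:]
    assert mc.call_variants(_consensus(tumor, [40] * 120), _consensus(normal, [40] * 120), EXON) == []


# ---------------------------------------------------------------------------
# codon mapping and effects
# ---------------------------------------------------------------------------

def test_map_to_codon_worked_examples():
    assert mc.map_to_codon(2549) == (850, 2)
    assert mc.map_to_codon(1) == (1, 1)
    assert mc.map_to_codon(3) == (1, 3)
    assert mc.map_to_codon(8529) == (2843, 3)


def test_map_to_codon_round_trip_identity():
    for p in range(1, 10_001):
        codon, offset = mc.map_to_codon(p)
        assert 3 * (codon - 1) + offset == p
    with pytest.raises(ValueError):
        mc.map_to_codon(0)


def _cds_with_codon(codon_index, codon, total_codons):
    filler = "GCT"  # alanine
    return filler * (codon_index - 1) + codon + filler * (total_codons - codon_index)


def test_nonsense_at_codon_850_from_TTG_to_TAG():
    """The classic T->A at CDS base 2549 turns leucine TTG into stop TAG."""
    cds = _cds_with_codon(850, "TTG", 2843)
    assert len(cds) == 8529
    v = mc.VariantCall("GENE", 2549, "T", "A", "substitution", 46)
    exon = mc.ExonModel("GENE", 1, "cds", 0, len(cds), "+", coding=True, cds_offset=1)
    assert mc.classify_effect(v, exon, cds) == mc.MutationEffect.NONSENSE


@pytest.mark.parametrize(
    "kind,ref,alt,expected",
    [
        ("insertion", "-", "GG", mc.MutationEffect.FRAMESHIFT),
        ("deletion", "GCT", "-", mc.MutationEffect.INFRAME_INDEL),
        ("insertion", "-", "G", mc.MutationEffect.FRAMESHIFT),
        ("deletion", "GCTGCTG", "-", mc.MutationEffect.FRAMESHIFT),
    ],
)
def test_indel_frameshift_rule(kind, ref, alt, expected):
    v = mc.VariantCall("GENE", 10, ref, alt, kind, 40)
    exon = mc.ExonModel("GENE", 1, "cds", 0, 300, "+", coding=True, cds_offset=1)
    assert mc.classify_effect(v, exon) == expected


def test_noncoding_exon_variant_is_noncoding():
    v = mc.VariantCall("GENE", 10, "T", "A", "substitution", 40)
    exon = mc.ExonModel("GENE", 1, "utr", 0, 300, "+", coding=False)
    assert mc.classify_effect(v, exon) == mc.MutationEffect.NONCODING


def test_synonymous_and_missense_classification():
    cds = "ATGCTGGCT"  # M L A
    exon = mc.ExonModel("GENE", 1, "cds", 0, 9, "+", coding=True, cds_offset=1)
    syn_v = mc.VariantCall("GENE", 6, "G", "A", "substitution", 40)  # CTG->CTA, still Leu
    mis_v = mc.VariantCall("GENE", 7, "G", "C", "substitution", 40)  # GCT->CCT, Ala->Pro
    assert mc.classify_effect(syn_v, exon, cds) == mc.MutationEffect.SYNONYMOUS
    assert mc.classify_effect(mis_v, exon, cds) == mc.MutationEffect.MISSENSE


def test_variant_outside_cds_raises():
    v = mc.VariantCall("GENE", 400, "T", "A", "substitution", 40)
    exon = mc.ExonModel("GENE", 1, "cds", 0, 300, "+", coding=True, cds_offset=1)
    with pytest.raises(ValueError, match="outside"):
        mc.classify_effect(v, exon, "GCT" * 100)


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def test_success_rates_match_printed_bookkeeping():
    mouse = mc.summarize_cohort({}, [True] * 3076 + [False] * (3264 - 3076))
    human = mc.summarize_cohort({}, [True] * 8342 + [False] * (9360 - 8342))
    assert mouse.success_rate_pct == 94
    assert human.success_rate_pct == 89


def test_empty_cohort_rate_flagged_undefined():
    summary = mc.summarize_cohort({}, [])
    assert summary.rate_undefined and summary.success_rate_pct is None


def test_truncating_counts_per_gene():
    v_non = mc.VariantCall("G1", 10, "T", "A", "substitution", 40)
    v_fs = mc.VariantCall("G1", 20, "-", "GG", "insertion", 40)
    v_mis = mc.VariantCall("G2", 5, "G", "C", "substitution", 40)
    calls = {
        "s1": [(v_non, mc.MutationEffect.NONSENSE), (v_fs, mc.MutationEffect.FRAMESHIFT)],
        "s2": [(v_mis, mc.MutationEffect.MISSENSE)],
        "s3": [],
    }
    summary = mc.summarize_cohort(calls, [True] * 10, genes=["G1", "G2"])
    assert summary.prevalence("G1") == (1, 3)  # one sample, counted once
    assert summary.prevalence("G2") == (0, 3)  # missense is not truncating


# ---------------------------------------------------------------------------
# end-to-end recovery on noise-free fixtures
# ---------------------------------------------------------------------------

def test_injected_variants_recovered_through_full_chain():
    cds = sim.simulate_cds_sequences(["G"], cds_length=300, seed=1)["G"]
    lesions = [(150, cds[149], "A" if cds[149] != "A" else "T", "substitution"),
               (90, "-", "GG", "insertion")]
    tumor_seq = sim.apply_variants(cds, lesions)
    cfg = sim.TraceSimConfig(quality_profile=np.full(400, 60))
    exon = mc.ExonModel("G", 1, "cds", 0, 300, "+", coding=True, cds_offset=1)
    calls = {}
    for tissue, seq in (("normal", cds), ("tumor", tumor_seq)):
        fwd, rev = sim.simulate_trace_pair(seq, cfg, seed=4)
        calls[tissue] = mc.assemble_exon_consensus(fwd, rev, reference=cds)
    found = mc.call_variants(calls["tumor"], calls["normal"], exon)
    got = {(v.cds_pos, v.ref, v.alt, v.kind) for v in found}
    assert got == set(lesions)


@pytest.mark.parametrize("seed", range(6))
def test_no_signal_null_zero_calls_any_seed(seed):
    """Tumor == normal through the whole chain never produces a call."""
    cds = sim.simulate_cds_sequences(["G"], cds_length=300, seed=seed)["G"]
    cfg = sim.TraceSimConfig()
    exon = mc.ExonModel("G", 1, "cds", 0, 300, "+", coding=True, cds_offset=1)
    gen = np.random.default_rng(seed)
    fwd_t, rev_t = sim.simulate_trace_pair(cds, cfg, gen)
    fwd_n, rev_n = sim.simulate_trace_pair(cds, cfg, gen)
    tumor = mc.assemble_exon_consensus(fwd_t, rev_t, reference=cds)
    normal = mc.assemble_exon_consensus(fwd_n, rev_n, reference=cds)
    assert mc.call_variants(tumor, normal, exon) == []
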