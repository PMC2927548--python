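"""Simulator contracts: determinism, the distance-decay rate law, the phred
error model, repeat-density targets, and aCGH truth bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

from xenopass import simcohort as sim
from xenopass import synteny as syn


# ---------------------------------------------------------------------------
# ortholog genomes and rearrangements
# ---------------------------------------------------------------------------

def test_zero_rearrangements_gives_identical_genomes():
    config = sim.GenomeSimConfig(n_genes=12, seed=7)
    frame_a, frame_b, omap, events = sim.simulate_ortholog_genomes(config)
    assert events == []
    pd.testing.assert_frame_equal(
        frame_a.drop(columns="genome"), frame_b.drop(columns="genome")
    )


def test_same_seed_gives_byte_identical_outputs():
    config = sim.GenomeSimConfig(n_genes=15, seed=3)
    a1, b1, _, _ = sim.simulate_ortholog_genomes(config)
    a2, b2, _, _ = sim.simulate_ortholog_genomes(config)
    pd.testing.assert_frame_equal(a1, a2)
    pd.testing.assert_frame_equal(b1, b2)


def test_apc_mcc_scenario_distance_asymmetry(apc_mcc):
    omap, _, roles = apc_mcc
    d_a = syn.gene_pair_distance(roles["driver"], roles["passenger"], "human_like", omap)
    d_b = syn.gene_pair_distance(roles["driver"], roles["passenger"], "mouse_like", omap)
    assert d_a < 2e5
    assert d_b >= 1e7


def test_inversion_round_trip_restores_gene_order():
    inv = sim.RearrangementEvent("inversion", "chr1", 5_000_000, 20_000_000)
    fixed = {f"G{i}": ("chr1", 6_000_000 + i * 1_000_000, "+") for i in range(8)}
    config = sim.GenomeSimConfig(
        n_chromosomes=1, chrom_length=40_000_000, n_genes=8, fixed_genes=fixed,
        rearrangements=[inv, ], seed=0,
    )
    _, once, _, _ = sim.simulate_ortholog_genomes(config)
    # apply the same inversion to the derived genome: back to the original
    config2 = sim.GenomeSimConfig(
        n_chromosomes=1, chrom_length=40_000_000, n_genes=8,
        fixed_genes={r.gene_id: (r.chrom, r.start, r.strand) for r in once.itertuples(index=False)},
        rearrangements=[inv], seed=0,
    )
    base, twice, _, _ = sim.simulate_ortholog_genomes(config2)
    original = {g: (c, s, st) for g, (c, s, st) in fixed.items()}
    roundtrip = {r.gene_id: (r.chrom, r.start, r.strand) for r in twice.itertuples(index=False)}
    assert roundtrip == original


def test_overlapping_rearrangements_rejected():
    events = [
        sim.RearrangementEvent("inversion", "chr1", 1_000_000, 5_000_000),
        sim.RearrangementEvent("inversion", "chr1", 4_000_000, 9_000_000),
    ]
    with pytest.raises(ValueError, match="overlapping"):
        sim.simulate_ortholog_genomes(sim.GenomeSimConfig(rearrangements=events))


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("total,alu", [(0.61, 0.26), (1.0, 0.26)])
def test_repeat_density_targets_recovered(total, alu):
    interval = ("chr1", 112_020_000, 112_220_000)  # 200 kb breakpoint interval
    repeats = sim.simulate_repeat_annotation([interval], total, alu, seed=11)
    assert abs(syn.repeat_density(interval, repeats) - total) <= 0.05
    assert abs(syn.repeat_density(interval, repeats, family="Alu") - alu) <= 0.05


def test_repeat_density_zero_target_yields_no_records():
    repeats = sim.simulate_repeat_annotation([("chr1", 0, 100_000)], 0.0, 0.0, seed=1)
    assert repeats.empty


def test_repeat_interval_shorter_than_repeat_warns_and_is_empty():
    with pytest.warns(UserWarning, match="minimum repeat length"):
        repeats = sim.simulate_repeat_annotation([("chr1", 0, 50)], 0.5, 0.1, seed=1)
    assert repeats.empty


# ---------------------------------------------------------------------------
# proximity rate law
# ---------------------------------------------------------------------------

def _empirical_rate(omap, gene, genome, config, n_tumors, seed):
    truth = sim.simulate_tumor_cohort(
        omap, [genome], config, n_tumors, seed=seed, genes=[gene]
    )
    return len(truth[truth["gene"] == gene]["tumor"].unique()) / n_tumors


def test_rate_law_matches_closed_form_near_driver(apc_mcc):
    """Gene 180 kb from the driver: rate = 0.01 + 0.5 exp(-0.36) ~ 0.359."""
    omap, _, roles = apc_mcc
    config = sim.ProximityModelConfig(
        background_rate=0.01, amplitude=0.5, decay_length=500_000.0,
        driver_genes=(roles["driver"],),
    )
    d = syn.gene_pair_distance(roles["passenger"], roles["driver"], "human_like", omap)
    expected = 0.01 + 0.5 * math.exp(-d / 500_000.0)
    n = 10_000
    emp = _empirical_rate(omap, roles["passenger"], "human_like", config, n, seed=5)
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(emp - expected) <= 3 * se


def test_rate_law_reduces_to_background_far_from_driver(apc_mcc):
    """Same gene 10.5 Mb away: excess exp(-21) is negligible, rate ~ beta."""
    omap, _, roles = apc_mcc
    config = sim.ProximityModelConfig(driver_genes=(roles["driver"],))
    n = 10_000
    emp = _empirical_rate(omap, roles["passenger"], "mouse_like", config, n, seed=6)
    se = math.sqrt(0.01 * 0.99 / n)
    assert abs(emp - 0.01) <= 3 * se


def test_rate_law_limit_lambda_to_zero(apc_mcc):
    omap, _, roles = apc_mcc
    config = sim.ProximityModelConfig(
        decay_length=1e-9, driver_genes=(roles["driver"],), background_rate=0.05
    )
    rate = sim.proximity_rate(roles["passenger"], "human_like", omap, config)
    assert rate == pytest.approx(0.05)


def test_missing_driver_gene_raises(apc_mcc):
    omap, _, _ = apc_mcc
    config = sim.ProximityModelConfig(driver_genes=("NO_SUCH_GENE",))
    with pytest.raises(ValueError, match="NO_SUCH_GENE"):
        sim.simulate_tumor_cohort(omap, ["human_like"], config, 5, seed=0)


def test_truth_table_lesions_apply_cleanly(apc_mcc):
    """Every recorded lesion is consistent with the reference CDS it names."""
    omap, _, roles = apc_mcc
    panel = [roles["driver"], roles["passenger"]]
    cds = sim.simulate_cds_sequences(panel, seed=2)
    config = sim.ProximityModelConfig(driver_genes=(roles["driver"],))
    truth = sim.simulate_tumor_cohort(
        omap, ["human_like"], config, 30, seed=2, cds_sequences=cds, genes=panel
    )
    assert not truth.empty
    for (tumor, gene), grp in truth.groupby(["tumor", "gene"]):
        mutated = sim.apply_variants(
            cds[gene], [(int(r.cds_pos), r.ref, r.alt, r.kind) for r in grp.itertuples(index=False)]
        )
        assert mutated != cds[gene]


# ---------------------------------------------------------------------------
# trace reads
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("q", [10, 20, 30])
def test_trace_error_rate_matches_phred_model(q, rng):
    truth = "".join(rng.choice(list("ACGT"), size=2000))
    cfg = sim.TraceSimConfig(quality_profile=np.full(2000, q))
    mismatches = bases = 0
    gen = np.random.default_rng(q * 101)
    for _ in range(30):
        fwd, rev = sim.simulate_trace_pair(truth, cfg, gen)
        rc = fwd.bases
        mismatches += sum(a != b for a, b in zip(rc, truth))
        from xenopass.mutcall import revcomp

        mismatches += sum(a != b for a, b in zip(revcomp(rev.bases), truth))
        bases += 2 * len(truth)
    p = 10 ** (-q / 10)
    se = math.sqrt(p * (1 - p) / bases)
    assert abs(mismatches / bases - p) <= 3 * se


def test_high_quality_traces_reproduce_truth():
    truth = "ACGTACGTACGTACGTACGT" * 5
    cfg = sim.TraceSimConfig(quality_profile=np.full(100, 60))
    fwd, rev = sim.simulate_trace_pair(truth, cfg, seed=0)
    from xenopass.mutcall import revcomp

    assert fwd.bases == truth
    assert revcomp(rev.bases) == truth


def test_trace_pair_deterministic_given_seed():
    truth = "ACGT" * 60
    cfg = sim.TraceSimConfig()
    r1 = sim.simulate_trace_pair(truth, cfg, seed=9)
    r2 = sim.simulate_trace_pair(truth, cfg, seed=9)
    assert r1[0].bases == r2[0].bases and r1[1].bases == r2[1].bases
    assert (r1[0].qualities == r2[0].qualities).all()


def test_empty_truth_yields_flagged_empty_reads():
    fwd, rev = sim.simulate_trace_pair("", sim.TraceSimConfig(), seed=0)
    assert len(fwd) == 0 and len(rev) == 0
    assert "failed" in fwd.id


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def test_ct_table_no_effect_no_noise_identical_tissues():
    table = sim.simulate_ct_table(["G1", "REF"], 4, effects={}, replicate_sd=0.0, seed=0)
    wide = table.pivot_table(index=["pair_id", "gene"], columns="tissue", values="ct1")
    assert (wide["tumor"] == wide["normal"]).all()
    # sd 0 -> all replicates identical
    assert (table["ct1"] == table["ct2"]).all() and (table["ct2"] == table["ct3"]).all()


def test_ct_table_effect_shifts_tumor_only():
    table = sim.simulate_ct_table(
        ["TGT", "REF"], 500, effects={"TGT": 1.0}, replicate_sd=0.1, seed=4
    )
    means = table.set_index(["gene", "tissue"]).groupby(level=[0, 1])[["ct1", "ct2", "ct3"]].mean().mean(axis=1)
    assert means.loc[("TGT", "tumor")] - means.loc[("TGT", "normal")] == pytest.approx(1.0, abs=0.05)
    assert means.loc[("REF", "tumor")] - means.loc[("REF", "normal")] == pytest.approx(0.0, abs=0.05)


# ---------------------------------------------------------------------------
# aCGH
# ---------------------------------------------------------------------------

def test_cgh_probe_count_matches_spacing():
    profile, _ = sim.simulate_cgh_profile(
        sim.CghSimConfig(genome_length=100_000_000, probe_spacing=5_000, altered_fraction=0.0)
    )
    assert len(profile) == 20_000


def test_cgh_zero_fraction_is_pure_noise():
    profile, truth = sim.simulate_cgh_profile(sim.CghSimConfig(altered_fraction=0.0, seed=1))
    assert truth.empty
    assert abs(profile["log2_ratio"].mean()) < 0.01


def test_cgh_truth_fraction_exact():
    cfg = sim.CghSimConfig(altered_fraction=0.04, seed=2)
    _, truth = sim.simulate_cgh_profile(cfg)
    realized = (truth["end"] - truth["start"]).sum() / cfg.genome_length
    assert realized == pytest.approx(0.04, abs=cfg.segment_length_range[1] / cfg.genome_length)


def test_cgh_invalid_segment_length_raises():
    with pytest.raises(ValueError, match="segment length"):
        sim.CghSimConfig(altered_fraction=0.1, segment_length_range=(100, 1000), probe_spacing=5000)
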