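"""Fuse per-species alteration evidence with synteny context into
driver / passenger / unresolved verdicts.

The cross-species logic: a gene altered in two or more species is a driver
candidate (recurrence across species is unlikely for collateral damage);
a gene altered in exactly one species, sitting near an altered driver locus
in that species but far from every altered driver in a species where it is
intact, is a proximity-passenger candidate; anything else is unresolved.
Species-specific drivers are by construction not identifiable this way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from . import cgh as _cgh
from . import mutcall as mc
from . import qpcr as _qpcr
from . import simcohort as sim
from . import synteny as syn

ALTERED, INTACT, UNKNOWN = "altered", "intact", "unknown"
_CHANNELS = ("sequence", "expression", "copy_number")


@dataclass
class SpeciesEvidence:
    sequence: str = UNKNOWN
    expression: str = UNKNOWN
    copy_number: str = UNKNOWN
    truncating_k: int | None = None
    truncating_n: int | None = None

    def __post_init__(self) -> None:
        for ch in _CHANNELS:
            if getattr(self, ch) not in (ALTERED, INTACT, UNKNOWN):
                raise ValueError(f"bad status for {ch}: {getattr(self, ch)!r}")
        if (
            self.truncating_k is not None
            and self.truncating_n is not None
            and self.truncating_k > self.truncating_n
        ):
            raise ValueError("truncating prevalence k cannot exceed n")

    @property
    def altered(self) -> bool:
        return any(getattr(self, ch) == ALTERED for ch in _CHANNELS)

    @property
    def observed_intact(self) -> bool:
        return not self.altered and any(getattr(self, ch) == INTACT for ch in _CHANNELS)


@dataclass
class GeneEvidence:
    gene: str
    per_species: dict[str, SpeciesEvidence]


@dataclass
class SyntenyContext:
    """Per-species distance (bp) to the nearest *altered* known-driver locus
    (inf when none / unlinked) and the region-instability verdict."""

    gene: str
    distance_to_altered_driver: dict[str, float]
    region_unstable: bool = True


@dataclass
class DriverCall:
    gene: str
    verdict: str  # 'driver_candidate' | 'passenger_candidate' | 'unresolved'
    rule: str
    rationale: str


def alteration_status(
    k: int,
    n: int,
    background_rate: float = 0.01,
    alpha: float = 0.05,
) -> str:
    """Sequence-channel status from truncating prevalence (k of n tumors).

    One-sided binomial test of prevalence above the background truncating rate:
    'altered' iff P(X >= k | n, background) < alpha.  n = 0 (untested) maps to
    'unknown'.
    """
    if n is None or n == 0:
        return UNKNOWN
    if k < 0 or k > n:
        raise ValueError("need 0 <= k <= n")
    p = _sstats.binomtest(k, n, background_rate, alternative="greater").pvalue
    return ALTERED if p < alpha else INTACT


def integrate_gene_call(
    evidence: GeneEvidence,
    context: SyntenyContext,
    d_near: float = 1_000_000.0,
    d_far: float = 5_000_000.0,
) -> DriverCall:
    """Apply the cross-species decision rules, in order, to one gene.

    1. recurrent: altered (any channel) in >= 2 species -> driver_candidate.
    2. proximity-passenger: altered in exactly one species AND within
       ``d_near`` of an altered driver there AND observed intact in some
       species where it lies >= ``d_far`` from every altered driver.
    3. otherwise unresolved.  Exactly one rule fires; the rationale names it
    and the thresholds used.
    """
    species = list(evidence.per_species)
    if len(species) < 2:
        raise ValueError("cross-species classification needs evidence for >= 2 species")
    altered_in = [s for s in species if evidence.per_species[s].altered]
    if len(altered_in) >= 2:
        return DriverCall(
            evidence.gene,
            "driver_candidate",
            "recurrent_across_species",
            f"rule=recurrent_across_species: altered in {sorted(altered_in)}",
        )
    if len(altered_in) == 1:
        s1 = altered_in[0]
        d1 = context.distance_to_altered_driver.get(s1, math.inf)
        far_intact = [
            s
            for s in species
            if s != s1
            and evidence.per_species[s].observed_intact
            and context.distance_to_altered_driver.get(s, math.inf) >= d_far
        ]
        if d1 <= d_near and far_intact:
            return DriverCall(
                evidence.gene,
                "passenger_candidate",
                "proximity_passenger",
                (
                    f"rule=proximity_passenger: altered only in {s1} at "
                    f"{d1:.0f} bp from an altered driver (d_near={d_near:.0f}); "
                    f"intact in {sorted(far_intact)} at >= d_far={d_far:.0f} bp"
                ),
            )
    return DriverCall(
        evidence.gene,
        "unresolved",
        "insufficient_evidence",
        f"rule=insufficient_evidence: altered in {sorted(altered_in)} species",
    )


def build_synteny_context(
    gene: str,
    drivers_altered_by_species: Mapping[str, Sequence[str]],
    omap: syn.OrthologMap,
    genome_of_species: Mapping[str, str],
    region_unstable: bool = True,
) -> SyntenyContext:
    """Distance from ``gene`` to the nearest altered driver, per species."""
    dist: dict[str, float] = {}
    for species, drivers in drivers_altered_by_species.items():
        genome = genome_of_species[species]
        best = math.inf
        for drv in drivers:
            if drv == gene:
                continue
            if omap.has(gene, genome) and omap.has(drv, genome):
                best = min(best, syn.gene_pair_distance(gene, drv, genome, omap))
        dist[species] = best
    return SyntenyContext(gene, dist, region_unstable)


# ---------------------------------------------------------------------------
# end-to-end pipeline on simulated cohorts
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Study design for the simulated cross-species comparison.

    Two species' tumor cohorts are generated under the proximity model on the
    packaged two-genome scenario, paired tumor/normal reads are simulated for
    each panel gene, and the mutation-calling, prevalence-testing and
    classification stages run on the simulated data.
    """

    species: tuple[str, str] = ("human_like", "mouse_like")
    n_tumors: int = 20
    cds_length: int = 300
    proximity: sim.ProximityModelConfig = field(
        default_factory=lambda: sim.ProximityModelConfig(driver_genes=("DRV1",))
    )
    trace: sim.TraceSimConfig = field(default_factory=sim.TraceSimConfig)
    qmin: int = 20
    min_hq_bases: int = 100
    background_rate_null: float = 0.01
    alpha_binomial: float = 0.05
    d_near: float = 1_000_000.0
    d_far: float = 5_000_000.0
    known_drivers: tuple[str, ...] | None = None  # None -> two-pass inference


@dataclass
class ReportBundle:
    config: PipelineConfig
    seed: int
    omap: syn.OrthologMap
    events: list
    roles: dict[str, str]
    truth: pd.DataFrame
    summaries: dict[str, mc.CohortSummary]
    evidence: dict[str, GeneEvidence]
    contexts: dict[str, SyntenyContext]
    calls: dict[str, DriverCall]

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for gene, call in self.calls.items():
            ev = self.evidence[gene]
            row = {"gene": gene, "verdict": call.verdict, "rule": call.rule}
            for species, se in ev.per_species.items():
                row[f"{species}_k"] = se.truncating_k
                row[f"{species}_n"] = se.truncating_n
                row[f"{species}_sequence"] = se.sequence
            rows.append(row)
        return pd.DataFrame(rows)


def _sequence_gene_cohort(
    cds: str,
    truth_rows: pd.DataFrame,
    gene: str,
    n_tumors: int,
    genome: str,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[tuple[mc.VariantCall, mc.MutationEffect]]], list[bool]]:
    """Simulate reads + call variants for one gene across a species' cohort."""
    exon = mc.ExonModel(gene, 1, "cds", 0, len(cds), "+", coding=True, cds_offset=1)
    calls_by_sample: dict[str, list[tuple[mc.VariantCall, mc.MutationEffect]]] = {}
    success_flags: list[bool] = []
    for t in range(n_tumors):
        tumor_id = f"{genome}_T{t + 1:03d}"
        muts = truth_rows[(truth_rows["tumor"] == tumor_id) & (truth_rows["gene"] == gene)]
        tumor_seq = sim.apply_variants(
            cds, [(int(r.cds_pos), r.ref, r.alt, r.kind) for r in muts.itertuples(index=False)]
        )
        sample_calls: list[tuple[mc.VariantCall, mc.MutationEffect]] = []
        consensi = {}
        for tissue, seq in (("normal", cds), ("tumor", tumor_seq)):
            fwd, rev = sim.simulate_trace_pair(seq, config.trace, rng, read_id=f"{tumor_id}.{gene}.{tissue}")
            for read in (fwd, rev):
                success_flags.append(
                    mc.read_is_successful(read, config.min_hq_bases, hq_threshold=config.qmin)
                )
            consensi[tissue] = mc.assemble_exon_consensus(
                fwd, rev, reference=cds, min_hq_bases=config.min_hq_bases, hq_threshold=config.qmin
            )
        if consensi["tumor"].success and consensi["normal"].success:
            for v in mc.call_variants(consensi["tumor"], consensi["normal"], exon, qmin=config.qmin):
                effect = mc.classify_effect(v, exon, cds)
                sample_calls.append((v, effect))
        calls_by_sample[tumor_id] = sample_calls
    return calls_by_sample, success_flags


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0) -> ReportBundle:
    """Simulate the two-species study and classify every panel gene.

    Stages run in dependency order: genome/scenario simulation, cohort
    mutagenesis under the proximity model, per-exon trace simulation, mutation
    calling, prevalence testing per species, synteny-context construction
    (two-pass driver seeding unless ``known_drivers`` is set), and rule-based
    integration.  Deterministic given ``seed``.
    """
    if config is None:
        config = PipelineConfig()
    ss = np.random.SeedSequence(seed)
    s_scen, s_cds, s_cohort, s_reads = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))

    omap, events, roles = sim.apc_mcc_scenario(seed=s_scen, genome_ids=config.species)
    panel = [roles["driver"], roles["passenger"], roles["control"]]
    cds_seqs = sim.simulate_cds_sequences(panel, cds_length=config.cds_length, seed=s_cds)
    truth = sim.simulate_tumor_cohort(
        omap,
        list(config.species),
        config.proximity,
        config.n_tumors,
        seed=s_cohort,
        cds_sequences=cds_seqs,
        genes=panel,
    )

    read_rng = np.random.default_rng(s_reads)
    summaries: dict[str, mc.CohortSummary] = {}
    for species in config.species:
        truth_rows = truth[truth["genome"] == species]
        calls_all: dict[str, list[tuple[mc.VariantCall, mc.MutationEffect]]] = {}
        flags_all: list[bool] = []
        for gene in panel:
            gene_calls, flags = _sequence_gene_cohort(
                cds_seqs[gene], truth_rows, gene, config.n_tumors, species, config, read_rng
            )
            for sample, calls in gene_calls.items():
                calls_all.setdefault(sample, []).extend(calls)
            flags_all.extend(flags)
        summaries[species] = mc.summarize_cohort(calls_all, flags_all, genes=panel)

    evidence: dict[str, GeneEvidence] = {}
    for gene in panel:
        per_species: dict[str, SpeciesEvidence] = {}
        for species in config.species:
            k, n = summaries[species].prevalence(gene)
            status = alteration_status(k, n, config.background_rate_null, config.alpha_binomial)
            per_species[species] = SpeciesEvidence(sequence=status, truncating_k=k, truncating_n=n)
        evidence[gene] = GeneEvidence(gene, per_species)

    # pass 1: seed the altered-driver set (supplied, or rule-1 recurrents)
    if config.known_drivers is not None:
        driver_set = list(config.known_drivers)
    else:
        driver_set = [
            g
            for g in panel
            if sum(evidence[g].per_species[s].altered for s in config.species) >= 2
        ]
    drivers_altered_by_species = {
        s: [g for g in driver_set if evidence[g].per_species[s].altered] for s in config.species
    }
    genome_of_species = {s: s for s in config.species}

    contexts: dict[str, SyntenyContext] = {}
    calls: dict[str, DriverCall] = {}
    for gene in panel:
        contexts[gene] = build_synteny_context(
            gene, drivers_altered_by_species, omap, genome_of_species
        )
        calls[gene] = integrate_gene_call(
            evidence[gene], contexts[gene], config.d_near, config.d_far
        )

    return ReportBundle(
        config=config,
        seed=seed,
        omap=omap,
        events=events,
        roles=roles,
        truth=truth,
        summaries=summaries,
        evidence=evidence,
        contexts=contexts,
        calls=calls,
    )
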