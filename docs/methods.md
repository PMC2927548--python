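# Methods

## Scope and design

`xenopass` turns a cross-species comparative-oncology strategy into a tested
pipeline. Because matched multi-species tumor data with per-base qualities is
rarely public, the package ships first-class simulators for every input and
validates each analysis stage by parameter recovery on that synthetic data.
All computation lives in `src/xenopass/`; the numbered scripts under
`analysis/` are thin narrative drivers that exercise it and write tables under
`results/`.

## Coordinates and randomness

Internally all coordinates are 0-based half-open. At file boundaries, BED
stays 0-based half-open while the ortholog/exon TSV dialects are 1-based
inclusive; conversions are centralized in `xenopass.io`. Every simulator
takes an integer seed and is deterministic given it; the integrated pipeline
derives per-stage sub-seeds from one seed via `numpy.random.SeedSequence`.

## Genome scenario

`simulate_ortholog_genomes` places non-overlapping genes on an ancestral
genome A and derives genome B by applying inversions (gene order reversed,
strands flipped, coordinates reflected within the interval) and
translocations. Events must not overlap each other or split a gene. The
packaged `apc_mcc_scenario` puts a driver-like gene and a passenger-like gene
180 kb apart on one chromosome of genome A and applies a ~10.4 Mb inversion
in the B lineage that relocates the passenger to ~10.5 Mb from the driver —
the adjacent-in-one-genome / distant-in-the-other configuration the
classifier needs — plus a control gene on another chromosome and background
genes on a 1-Mb grid.

## Synteny

Blocks are built from **gene order only** (no sequence alignment): genes
shared by two genomes are walked in genome-A order, and a block extends while
the signed within-chromosome rank in genome B (negative when the strand
relationship flips) increases by exactly one — the standard
signed-permutation run criterion. Blocks are maximal by construction, so any
two blocks adjacent on a reference chromosome delimit a breakpoint; the
breakpoint interval is the intergenic gap between the bounding genes.
Gene-pair distance is the absolute start-to-start difference, with an
infinite sentinel for different chromosomes — chosen so distance-decay terms
`exp(-d/λ)` vanish naturally for unlinked genes. A region is called
evolutionarily unstable when at least `min_species` (default 3) species have
a breakpoint within the region widened by a `flank` (default 5 Mb, since
breakpoints a few Mb away still indicate local instability). Repeat density
is union coverage, so overlapping records never double-count.

## Proximity mutagenesis model

Per tumor and gene, the truncating-lesion probability is
`β + Σ_drivers α·exp(−d/λ)` for non-drivers and `p_driver` for drivers.
Defaults — β = 0.01, α = 0.5, λ = 500 kb, p_driver = 0.9, 20 tumors per
species — are the package's study conditions: they put the adjacent-genome
passenger rate at `0.01 + 0.5·e^(−0.36) ≈ 0.36` (clearly detectable at 20
tumors) while the same gene 10.5 Mb away stays at the background 0.01, and
p_driver = 0.9 reflects a near-obligate driver lesion, as in tumors from a
germline-predisposed model or a gene mutated in the vast majority of sporadic
cases. Injected lesions are 50/50 nonsense substitutions (drawn uniformly
from all single-base changes that create a stop codon) versus 1–2 bp indels
at uniform CDS positions. Distances use gene 5′ starts, matching
`gene_pair_distance`.

## Reads, consensus and variant calling

Sanger-like reads carry a quality profile (default: phred 8 on the first and
last 15 bases, 45 in the interior) and per-base miscalls injected with
probability `10^(−Q/10)` — the phred convention, under which Q20 means ≤ 1%
error. Trimming retains the leftmost longest substring in which every
sliding window (default length 10) has mean quality ≥ 20; substrings shorter
than the window must pass on their own mean. Forward and reverse reads are
merged after global alignment: agreeing bases keep the max quality,
disagreements go to the higher-quality base, and exact quality ties become
`N` with quality 0 so they can never produce a variant call — a conservative
stand-in for manual trace inspection. A consensus "succeeds" with ≥ 100
bases at Q ≥ 20; the same rule applied per read defines the
attempt/success sequencing bookkeeping.

Because trimming removes read ends, the consensus is anchored to the
reference exon and its offset recorded, so variant positions are reported in
true CDS coordinates. Tumor and normal consensi are aligned globally
(match +1, mismatch −2, gap open −5 including the first gapped base, extend
−2; backed by Biopython's pairwise aligner, with optimality checked against
a brute-force enumeration oracle in the tests). A substitution is emitted
when both bases pass Q ≥ 20; an indel additionally requires every
inserted/deleted base *and* one flanking anchor column (both sequences) to
pass — the quality filter is defined for bases, so indels need an explicit
rule, and anchoring is the conservative choice. Effects: substitutions are
translated (standard codon table) into synonymous/missense/nonsense; coding
indels are frameshift iff length mod 3 ≠ 0; noncoding exons yield
`noncoding`. Truncating = nonsense + frameshift; missense and noncoding
changes are recorded but excluded from truncating summaries. CDS position
`p` maps to codon `⌈p/3⌉`, offset `((p−1) mod 3)+1`.

## qPCR / qRT-PCR

Technical replicates are averaged (flagged when one is missing or the sd
exceeds 0.5 cycles). ΔCt = target Ct − mean(reference Ct), which removes any
per-sample global additive shift exactly. Reference candidates are retained
when their raw tumor−normal paired difference is small (≤ 0.5 Ct) and
non-significant. Per gene, tumor−normal ΔCt differences get a paired t-test
(two-sided by default; one-sided and unpaired Welch variants are provided
because small paired designs are sometimes analyzed either way);
`altered` means p < α with α defaulting to 0.1 — a deliberate, prominently
configurable choice: in targeted confirmation assays on ~10 pairs, a p-value
just under 0.1 is already corroborating rather than hypothesis-generating
evidence. Benjamini–Hochberg adjusted p-values are reported alongside; calls
use raw p by default (a flag switches). Copy-number qPCR reuses the identical
machinery with reference *exons* in place of reference *genes*.

The Ct simulator draws a fixed baseline per gene, adds the configured tumor
effect, replicate noise (default sd 0.15 cycles), and optionally a per-sample
global shift (default 0). It does not model amplification-efficiency
differences or per-pair biological scatter, so simulated t statistics are
larger than typical cohort values at the same mean effect; tests therefore
check effect-size recovery and test calibration, not any particular t.

## aCGH segmentation

The segmentation is a purpose-built stand-in for unpublished in-house
segmentation software: recursive binary splitting at the maximal two-sample
t statistic, with each split accepted only if its permutation p-value (200
permutations by default) beats α_seg = 0.01, at least 5 probes per side
(~25 kb at the 5-kb spacing), recursing into both halves. Segments tile each
chromosome; a segment is gain/loss when its mean |log2 ratio| ≥ δ = 0.3 —
above the default noise sd of 0.15 but well below a single-copy change at
|0.8| — and the altered fraction pools gains and losses. CIN classes:
`none` below 0.02, `subtle` in [0.02, 0.10], `extensive` above 0.10. The
profile simulator places well-separated altered segments (0.5–2 Mb) whose
summed length matches the target fraction exactly, so recovery error
reflects the segmentation, not the truth construction. Validation: over
truth fractions {0, 0.01, 0.04, 0.10} the mean recovered fraction is within
±25% relative (±0.005 absolute at 0) across 10 seeds, and normal-vs-normal
profiles stay below a 0.02 false-call bound.

## Classification

Per species, the sequence channel is called by a one-sided binomial test of
truncating prevalence k/n against a background rate β₀ = 0.01 at α = 0.05:
`altered` iff P(X ≥ k) < α. Decision rules (exactly one fires per gene, in
order): (1) altered in ≥ 2 species → driver candidate; (2) altered in
exactly one species AND within D_near of an altered driver there AND
observed intact in some species ≥ D_far from every altered driver →
passenger candidate; (3) otherwise unresolved. D_near = 1 Mb and
D_far = 5 Mb bracket the scenario's 180 kb / 10.5 Mb anchor points and are
configurable; every rationale string records them. The altered-driver set is
either supplied (`known_drivers`) or inferred in a first pass as the rule-1
recurrents — the two-pass mode is the default. Channels corroborate; they
are not weighted or scored, and `unknown` never counts as intact.

## Problem sizes

Default study sizes keep the full simulation-and-analysis loop fast enough
to run many seeds: 20 tumors per species, one 300-bp coding exon per panel
gene, 100-Mb single-chromosome aCGH profiles at 5-kb spacing (20,000
probes). One end-to-end pipeline run takes under a second; a 10-profile
segmentation study takes ~25 s on one core.

## What the simulations do and do not show

Passing tests establish that each stage recovers what its generator injected
under the stated models: the rate law, the phred error model, exact-coverage
repeats, step-shaped copy-number segments, and additive Ct effects. Real
data violate these in known ways — chromatogram artifacts and heterozygous
mixed traces (the simulator never emits mixed bases), PCR/primer failures,
repeat *sequences* rather than annotated intervals, probe-level aCGH
artifacts and waviness, amplification-efficiency differences in qPCR, and
tumor heterogeneity with subclonal allele fractions. The classifier also
inherits the strategy's intrinsic blind spot: species-specific drivers are
unresolvable by design. Conclusions about any particular gene require real
cohorts; the package establishes that the inference machinery is correct and
calibrated, not that any biological claim is true.
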