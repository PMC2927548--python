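"""aCGH segmentation, altered-genome fraction, and CIN classification.

Profiles of per-probe log2 tumor/normal ratios are segmented by recursive
binary segmentation: at each step the split maximizing the two-sample t
statistic between the flanks is tested against a permutation null and
accepted when its permutation p-value beats ``alpha_seg``.  Segments whose
mean |log2 ratio| reaches a threshold δ count as gained/lost; the altered
fraction is their summed length over the genome length, and the
chromosomal-instability (CIN) class follows from that fraction ("subtle" for
a few percent, "extensive" above ten percent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    n_probes: int
    state: str  # 'gain' | 'loss' | 'neutral'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CinReport:
    altered_fraction: float
    cin_class: str  # 'none' | 'subtle' | 'extensive'


def _split_statistics(values: np.ndarray, min_probes: int) -> tuple[int, float] | None:
    """Best split index (left length) and |t| over all admissible splits."""
    n = values.size
    if n < 2 * min_probes:
        return None
    csum = np.cumsum(values)
    csq = np.cumsum(values * values)
    total, total_sq = csum[-1], csq[-1]
    k = np.arange(min_probes, n - min_probes + 1)
    sum_l = csum[k - 1]
    mean_l = sum_l / k
    mean_r = (total - sum_l) / (n - k)
    ss_l = csq[k - 1] - k * mean_l**2
    ss_r = (total_sq - csq[k - 1]) - (n - k) * mean_r**2
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.sqrt(np.maximum(ss_l + ss_r, 0.0) / df)
        t = np.abs(mean_l - mean_r) / (pooled * np.sqrt(1.0 / k + 1.0 / (n - k)))
    t = np.where(np.isnan(t), 0.0, t)  # constant halves with equal means
    best = int(np.argmax(t))
    return int(k[best]), float(t[best])


def _max_t_null(values: np.ndarray, min_probes: int, n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """Max-|t| distribution over index permutations of the probe values."""
    perms = np.tile(values, (n_permutations, 1))
    perms = rng.permuted(perms, axis=1)
    n = values.size
    csum = np.cumsum(perms, axis=1)
    csq = np.cumsum(perms * perms, axis=1)
    total = csum[:, -1:]
    total_sq = csq[:, -1:]
    k = np.arange(min_probes, n - min_probes + 1)
    sum_l = csum[:, k - 1]
    mean_l = sum_l / k
    mean_r = (total - sum_l) / (n - k)
    ss_l = csq[:, k - 1] - k * mean_l**2
    ss_r = (total_sq - csq[:, k - 1]) - (n - k) * mean_r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.sqrt(np.maximum(ss_l + ss_r, 0.0) / (n - 2))
        t = np.abs(mean_l - mean_r) / (pooled * np.sqrt(1.0 / k + 1.0 / (n - k)))
    t = np.where(np.isnan(t), 0.0, t)
    return t.max(axis=1)


def _state(mean: float, delta: float) -> str:
    if mean >= delta:
        return "gain"
    if mean <= -delta:
        return "loss"
    return "neutral"


def segment_profile(
    profile: pd.DataFrame,
    min_probes: int = 5,
    n_permutations: int = 200,
    alpha_seg: float = 0.01,
    seed: int = 0,
    delta: float = 0.3,
) -> list[Segment]:
    """Recursive binary segmentation of an aCGH profile.

    ``profile`` needs columns ``chrom, pos, log2_ratio`` with positions
    strictly increasing within each chromosome.  Each accepted split has a
    permutation p-value below ``alpha_seg``; chromosomes with fewer than
    ``2*min_probes`` probes remain single segments.  Deterministic given
    ``seed``.  Segment boundaries tile each chromosome: interior boundaries
    fall at the first probe of the right-hand segment, the ends extend to the
    probe extent plus one median spacing.
    """
    segments: list[Segment] = []
    rng = np.random.default_rng(seed)
    for chrom, grp in profile.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"probe positions not strictly increasing on {chrom}")
        values = grp["log2_ratio"].to_numpy(dtype=float)
        spacing = int(np.median(np.diff(pos))) if pos.size > 1 else 1
        cuts: list[int] = []  # probe indices starting a new segment

        def recurse(lo: int, hi: int) -> None:
            sub = values[lo:hi]
            found = _split_statistics(sub, min_probes)
            if found is None:
                return
            split, t_obs = found
            if t_obs <= 0:
                return
            null = _max_t_null(sub, min_probes, n_permutations, rng)
            p = (1 + int((null >= t_obs).sum())) / (n_permutations + 1)
            if p >= alpha_seg:
                return
            cuts.append(lo + split)
            recurse(lo, lo + split)
            recurse(lo + split, hi)

        recurse(0, values.size)
        bounds = [0] + sorted(cuts) + [values.size]
        for i0, i1 in zip(bounds, bounds[1:]):
            start = int(pos[i0]) if i0 > 0 else int(pos[0])
            end = int(pos[i1]) if i1 < values.size else int(pos[-1]) + spacing
            mean = float(values[i0:i1].mean())
            segments.append(Segment(chrom, start, end, mean, i1 - i0, _state(mean, delta)))
    return segments


def altered_fraction(segments: Sequence[Segment], delta: float = 0.3) -> float:
    """Summed length of gained/lost segments over the total tiled length.

    A segment counts as altered when its mean |log2 ratio| >= ``delta``;
    gains and losses are pooled.
    """
    total = sum(s.length for s in segments)
    if total == 0:
        return 0.0
    altered = sum(s.length for s in segments if abs(s.mean_log2) >= delta)
    return altered / total


def classify_cin(
    fraction: float,
    cut_subtle: float = 0.02,
    cut_extensive: float = 0.10,
) -> str:
    """CIN class from the altered fraction: none (< cut_subtle), subtle
    (between the cuts, inclusive) or extensive (> cut_extensive)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if fraction < cut_subtle:
        return "none"
    if fraction > cut_extensive:
        return "extensive"
    return "subtle"


def cin_report(segments: Sequence[Segment], delta: float = 0.3) -> CinReport:
    frac = altered_fraction(segments, delta)
    return CinReport(altered_fraction=frac, cin_class=classify_cin(frac))


def segments_to_frame(segments: Sequence[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "mean_log2": s.mean_log2, "n_probes": s.n_probes, "state": s.state}
            for s in segments
        ],
        columns=["chrom", "start", "end", "mean_log2", "n_probes", "state"],
    )
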