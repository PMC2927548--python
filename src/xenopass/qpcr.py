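"""ΔCt normalization and paired testing of qPCR / qRT-PCR measurements.

A Ct value is the threshold cycle of a quantitative PCR reaction; a higher Ct
means fewer templates.  Target genes are normalized against the mean Ct of a
reference-gene set (ΔCt = Ct_target − mean Ct_references), which removes any
per-sample global additive shift exactly.  Tumor-vs-normal differences in the
normalized values are tested per gene with a paired t-test.

The same machinery serves expression (qRT-PCR on cDNA, reference *genes*) and
copy number (qPCR on genomic DNA, reference *exons*): one code path, two
configurations — only the identifiers change.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedTestResult:
    gene: str
    n: int
    mean_diff: float
    t: float | None
    df: int
    p: float | None
    degenerate: bool = False


def aggregate_replicates(
    replicates: Sequence[float],
    sd_limit: float = 0.5,
) -> tuple[float, float, bool]:
    """Mean and sd of technical replicates with a QC flag.

    Missing replicates (NaN/None) are dropped; the flag is set when any
    replicate is missing or the sd of the remaining ones exceeds ``sd_limit``.
    All-missing input is an error.
    """
    values = np.array([np.nan if r is None else float(r) for r in replicates], dtype=float)
    present = values[~np.isnan(values)]
    if present.size == 0:
        raise ValueError("all replicates missing")
    mean = float(present.mean())
    sd = float(present.std(ddof=1)) if present.size > 1 else 0.0
    flagged = bool(present.size < values.size or sd > sd_limit)
    return mean, sd, flagged


def _replicate_columns(ct_table: pd.DataFrame) -> list[str]:
    cols = [c for c in ct_table.columns if c.startswith("ct")]
    if not cols:
        raise ValueError("Ct table has no replicate columns (ct1, ct2, ...)")
    return cols


def mean_ct_table(ct_table: pd.DataFrame, sd_limit: float = 0.5) -> pd.DataFrame:
    """Collapse replicate columns to one mean Ct per (pair, tissue, gene)."""
    cols = _replicate_columns(ct_table)
    rows = []
    for row in ct_table.itertuples(index=False):
        mean, sd, flagged = aggregate_replicates([getattr(row, c) for c in cols], sd_limit)
        rows.append(
            {"pair_id": row.pair_id, "tissue": row.tissue, "gene": row.gene,
             "ct": mean, "ct_sd": sd, "flagged": flagged}
        )
    return pd.DataFrame(rows)


def normalize_ct(sample_ct: Mapping[str, float], target: str, references: Sequence[str]) -> float:
    """ΔCt = Ct_target − mean(Ct of reference genes) for one sample."""
    if target not in sample_ct:
        raise KeyError(f"target {target!r} not measured in sample")
    missing = [r for r in references if r not in sample_ct]
    if missing:
        raise KeyError(f"reference(s) {missing} not measured in sample")
    return float(sample_ct[target]) - float(np.mean([sample_ct[r] for r in references]))


def delta_ct_table(
    ct_table: pd.DataFrame,
    target: str,
    references: Sequence[str],
) -> pd.DataFrame:
    """Per-sample ΔCt for one target; samples missing a reference are excluded
    with a warning.  Returns columns pair_id, tissue, delta_ct."""
    means = mean_ct_table(ct_table)
    rows = []
    for (pair, tissue), grp in means.groupby(["pair_id", "tissue"], sort=True):
        sample = dict(zip(grp["gene"], grp["ct"]))
        try:
            d = normalize_ct(sample, target, references)
        except KeyError as exc:
            warnings.warn(f"sample ({pair}, {tissue}) excluded: {exc}", stacklevel=2)
            continue
        rows.append({"pair_id": pair, "tissue": tissue, "delta_ct": d})
    return pd.DataFrame(rows)


def paired_differences(delta: pd.DataFrame) -> pd.Series:
    """Tumor minus normal ΔCt per pair (pairs missing a tissue are dropped)."""
    wide = delta.pivot(index="pair_id", columns="tissue", values="delta_ct").dropna()
    return wide["tumor"] - wide["normal"]


def paired_t_test(
    differences: Sequence[float],
    gene: str = "",
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Paired t-test on per-pair differences: t = mean(d) / (sd(d)/sqrt(n)).

    Zero-variance input is flagged degenerate (no p-value).  ``alternative``
    may be 'two-sided', 'greater' or 'less'.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedTestResult(gene, n, mean, None, n - 1, None, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    if alternative == "two-sided":
        p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    elif alternative == "greater":
        p = float(stats.t.sf(t, n - 1))
    elif alternative == "less":
        p = float(stats.t.cdf(t, n - 1))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PairedTestResult(gene, n, mean, float(t), n - 1, p)


def unpaired_t_test(tumor: Sequence[float], normal: Sequence[float], gene: str = "") -> PairedTestResult:
    """Welch two-sample variant, provided for designs without strict pairing."""
    res = stats.ttest_ind(np.asarray(tumor, float), np.asarray(normal, float), equal_var=False)
    mean = float(np.mean(tumor) - np.mean(normal))
    return PairedTestResult(gene, len(tumor), mean, float(res.statistic), int(res.df), float(res.pvalue))


def reference_stability(
    ct_table: pd.DataFrame,
    candidates: Sequence[str],
    mean_threshold: float = 0.5,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Select reference genes that are stable across tumor/normal pairs.

    A candidate is retained when the absolute mean paired tumor−normal Ct
    difference is <= ``mean_threshold`` and its paired test is non-significant
    at ``alpha``.  An empty retained set is an error instructing manual choice.
    """
    if not candidates:
        raise ValueError("need at least one candidate reference gene")
    means = mean_ct_table(ct_table)
    stats_rows = []
    retained: list[str] = []
    for gene in candidates:
        sub = means[means["gene"] == gene]
        wide = sub.pivot(index="pair_id", columns="tissue", values="ct").dropna()
        d = (wide["tumor"] - wide["normal"]).to_numpy()
        res = paired_t_test(d, gene=gene)
        stable = abs(res.mean_diff) <= mean_threshold and (res.degenerate or res.p >= alpha)
        if stable:
            retained.append(gene)
        stats_rows.append(
            {"gene": gene, "n": res.n, "mean_diff": res.mean_diff, "t": res.t,
             "p": res.p, "stable": stable}
        )
    if not retained:
        raise ValueError(
            "no candidate reference gene is stable; choose normalization controls manually"
        )
    return retained, pd.DataFrame(stats_rows)


def call_expression_alteration(result: PairedTestResult, alpha: float = 0.1) -> str:
    """'altered' iff p < alpha (strict), else 'intact'.

    The permissive default alpha reflects small paired cohorts where a
    sub-0.1 p-value on a targeted gene is already informative corroboration.
    """
    if result.degenerate or result.p is None:
        raise ValueError("cannot call alteration from a degenerate test result")
    return "altered" if result.p < alpha else "intact"


def analyze_panel(
    ct_table: pd.DataFrame,
    targets: Sequence[str],
    references: Sequence[str],
    alpha: float = 0.1,
    use_adjusted: bool = False,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-gene ΔCt paired tests with BH-adjusted p-values and calls.

    Calls use raw p-values by default; ``use_adjusted`` switches the call to
    the Benjamini-Hochberg adjusted values.
    """
    rows = []
    for gene in targets:
        d = paired_differences(delta_ct_table(ct_table, gene, references))
        res = paired_t_test(d.to_numpy(), gene=gene, alternative=alternative)
        rows.append(res)
    frame = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "n": [r.n for r in rows],
            "mean_diff": [r.mean_diff for r in rows],
            "t": [r.t for r in rows],
            "df": [r.df for r in rows],
            "p": [r.p for r in rows],
        }
    )
    valid = frame["p"].notna()
    frame["p_adj"] = np.nan
    if valid.any():
        frame.loc[valid, "p_adj"] = multipletests(frame.loc[valid, "p"], method="fdr_bh")[1]
    crit = frame["p_adj"] if use_adjusted else frame["p"]
    frame["call"] = np.where(crit < alpha, "altered", "intact")
    frame.loc[frame["p"].isna(), "call"] = "unknown"
    return frame
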