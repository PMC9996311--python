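"""Condition-level statistics: medians, fold changes, replicate tests, intensities.

Each experimental condition is summarized by the median per-trajectory
D_eff-5sec and α-5sec over all passing trajectories.  Conditions are compared
by the fold change of median D_eff (test over reference), computed per
biological replicate and then averaged (mean ± SD across replicates), and by
a paired two-tailed t test on the per-replicate medians.  With the typical
three replicates the t test has little power and its normality assumption is
untestable; it is reported as the field convention, not as a strong
inference.  Particle brightness — a proxy for particle size — is summarized
as the distribution of per-trajectory average mean intensities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError

__all__ = [
    "ConditionSummary",
    "TTestResult",
    "ComparisonResult",
    "IntensityDistribution",
    "summarize_condition",
    "fold_change",
    "paired_t_test",
    "compare_replicates",
    "intensity_distribution",
    "rank_sum_test",
]


@dataclasses.dataclass
class ConditionSummary:
    """Per-condition, per-replicate medians and the intensity vector."""

    condition: str
    replicate: str
    n_trajectories: int
    median_D_eff: float
    median_alpha: float
    intensity_values: np.ndarray


@dataclasses.dataclass
class TTestResult:
    """Paired two-tailed t test on per-replicate scalars."""

    t_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    degenerate: bool  # all paired differences identical: t undefined
    test: str = "paired two-tailed t"


@dataclasses.dataclass
class ComparisonResult:
    """Fold-change construction across replicates plus the paired tests."""

    fold_changes: np.ndarray  # one per replicate, test/reference
    mean_fold: float
    sd_fold: float
    t_statistic: float  # on paired raw medians
    p_value: float
    t_statistic_vs_unity: float  # on fold changes against 1
    p_value_vs_unity: float
    test: str = "paired two-tailed t"
    degenerate: bool = False


def summarize_condition(
    records: pd.DataFrame, condition: str, replicate: str = "1"
) -> ConditionSummary:
    """Summarize per-trajectory fit records for one condition/replicate.

    ``records`` is the per-trajectory table from
    :func:`mesorheo.msd.analyze_trajectories`.  Medians use the standard
    definition (mean of the central two values for even n); trajectories with
    NaN α are excluded from the α median only.
    """
    if len(records) == 0:
        raise ValueError(f"no trajectory records for condition {condition!r}")
    d = records["D_eff_um2_per_s"].to_numpy(dtype=float)
    a = records["alpha"].to_numpy(dtype=float)
    intens = (
        records["mean_intensity"].to_numpy(dtype=float)
        if "mean_intensity" in records
        else np.full(len(records), np.nan)
    )
    a_valid = a[~np.isnan(a)]
    return ConditionSummary(
        condition=condition,
        replicate=str(replicate),
        n_trajectories=len(records),
        median_D_eff=float(np.median(d)),
        median_alpha=float(np.median(a_valid)) if len(a_valid) else np.nan,
        intensity_values=intens[~np.isnan(intens)],
    )


def fold_change(test: ConditionSummary, reference: ConditionSummary) -> float:
    """Ratio of median D_eff, test over reference."""
    if not reference.median_D_eff > 0:
        raise ConfigError(
            f"reference condition {reference.condition!r} has non-positive median D_eff"
        )
    return test.median_D_eff / reference.median_D_eff


def paired_t_test(values_a: np.ndarray, values_b: np.ndarray) -> TTestResult:
    """Classical paired two-sided t test on per-replicate scalars.

    If every paired difference is identical (zero variance — including the
    all-zero case), the statistic is undefined: the result carries
    ``degenerate=True`` with NaN t and p rather than a silent p of 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equally long 1D vectors")
    if len(a) < 2:
        raise ValueError("paired test needs at least two replicate pairs")
    diffs = a - b
    base = TTestResult(
        t_statistic=np.nan, p_value=np.nan,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        degenerate=True,
    )
    if np.ptp(diffs) == 0.0:
        return base
    t_stat, p = stats.ttest_rel(a, b)
    base.t_statistic = float(t_stat)
    base.p_value = float(p)
    base.degenerate = False
    return base


def compare_replicates(
    test_summaries: list[ConditionSummary],
    reference_summaries: list[ConditionSummary],
) -> ComparisonResult:
    """Fold changes per replicate plus paired tests across replicates.

    Summaries are paired by their ``replicate`` labels.  Two t tests are
    reported: on the paired raw medians (test vs reference), and on the
    per-replicate fold changes against 1; they answer slightly different
    questions and both constructions appear in practice.
    """
    by_rep_test = {s.replicate: s for s in test_summaries}
    by_rep_ref = {s.replicate: s for s in reference_summaries}
    if set(by_rep_test) != set(by_rep_ref):
        raise ConfigError(
            f"replicate labels differ: {sorted(by_rep_test)} vs {sorted(by_rep_ref)}"
        )
    reps = sorted(by_rep_test)
    folds = np.array([fold_change(by_rep_test[r], by_rep_ref[r]) for r in reps])
    med_test = np.array([by_rep_test[r].median_D_eff for r in reps])
    med_ref = np.array([by_rep_ref[r].median_D_eff for r in reps])
    raw = paired_t_test(med_test, med_ref)
    vs_one = paired_t_test(folds, np.ones_like(folds))
    return ComparisonResult(
        fold_changes=folds,
        mean_fold=float(folds.mean()),
        sd_fold=float(folds.std(ddof=1)) if len(folds) > 1 else np.nan,
        t_statistic=raw.t_statistic,
        p_value=raw.p_value,
        t_statistic_vs_unity=vs_one.t_statistic,
        p_value_vs_unity=vs_one.p_value,
        degenerate=raw.degenerate,
    )


@dataclasses.dataclass
class IntensityDistribution:
    """Normalized brightness histogram with robust summary statistics."""

    bin_edges: np.ndarray
    mass: np.ndarray  # fraction of particles per bin; sums to 1
    median: float
    q25: float
    q75: float

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


def intensity_distribution(values: np.ndarray, bins: int = 30) -> IntensityDistribution:
    """Histogram (mass-normalized) and quantiles of per-particle intensities."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("empty intensity vector")
    counts, edges = np.histogram(values, bins=bins)
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return IntensityDistribution(
        bin_edges=edges,
        mass=counts / counts.sum(),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
    )


def rank_sum_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney rank-sum comparison of two intensity samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both intensity samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
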