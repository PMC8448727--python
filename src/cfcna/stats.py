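"""Cohort-level detection and comparison statistics.

Detection proportions use exact (Clopper-Pearson) binomial confidence
intervals; tumor-fraction summaries report median and IQR with the linear
interpolation quartile convention; cross-depth agreement uses Pearson
correlation; group comparisons use the Mann-Whitney U test (exact for
small tie-free samples) or the Wilcoxon signed-rank test when paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class DetectionThresholds:
    """Tumor-fraction detection cutoffs per depth (1% deep, 3% ULP)."""

    deep: float = 0.01
    ulp: float = 0.03

    def __post_init__(self) -> None:
        for v in (self.deep, self.ulp):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must be in (0, 1)")

    def for_depth(self, depth: str) -> float:
        if depth in ("deep", "30x"):
            return self.deep
        if depth in ("ulp", "0.1x"):
            return self.ulp
        raise ValueError(f"unknown depth label: {depth!r}")


def clopper_pearson_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta quantiles)."""
    k, n = int(successes), int(trials)
    if n < 1 or not 0 <= k <= n:
        raise ValueError("invalid counts")
    a = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(a / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1 - a / 2, k + 1, n - k))
    return lower, upper


class DetectionSummary(NamedTuple):
    count: int
    trials: int
    percent: int
    ci_percent: tuple[int, int]


def detection_summary(
    cohort: pd.DataFrame, depth: str, thresholds: DetectionThresholds
) -> DetectionSummary:
    """Count patients at or above the depth's detection cutoff.

    ``cohort`` needs a ``tumor_fraction_deep`` / ``tumor_fraction_ulp``
    column for the requested depth.  Percentages (and the CI) are rounded
    to the nearest integer percent.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    col = "tumor_fraction_deep" if depth in ("deep", "30x") else "tumor_fraction_ulp"
    if col not in cohort.columns:
        raise ValueError(f"cohort table lacks column {col!r}")
    tf = cohort[col].astype(float)
    cutoff = thresholds.for_depth(depth)
    count = int((tf >= cutoff).sum())
    trials = int(len(tf))
    lo, hi = clopper_pearson_ci(count, trials)
    return DetectionSummary(
        count=count,
        trials=trials,
        percent=round(100.0 * count / trials),
        ci_percent=(round(100.0 * lo), round(100.0 * hi)),
    )


def summarize_tf(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Median and (Q1, Q3) with linear interpolation."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def correlate_depths(
    tf_deep: Sequence[float], tf_ulp: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and two-sided p-value between paired tumor fractions."""
    a = np.asarray(list(tf_deep), dtype=float)
    b = np.asarray(list(tf_ulp), dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate input")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], paired: bool = False
) -> float:
    """Two-sided rank-based group comparison p-value.

    Unpaired: Mann-Whitney U, exact when the combined sample is small
    (n <= 12) and tie-free, otherwise the tie-corrected normal
    approximation.  Paired: Wilcoxon signed-rank.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    if paired:
        return float(sps.wilcoxon(a, b, alternative="two-sided").pvalue)
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
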