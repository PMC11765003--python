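"""Diagnostic-accuracy statistics and spike-mixture summaries.

Confusion counts are pooled over per-SNV calls across families and
replicates (not averaged per family).  Sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP), with exact binomial (Clopper-Pearson) 95%
confidence intervals.  Spike-mixture experiments — two genomic DNAs blended
at a known minority ratio to mimic the fetomaternal composition of cfDNA —
are summarised by the mean ± 1 SD band of per-site minor-genotype
fractions; the assay is considered to resolve a spike level when the
expected fraction falls inside (or negligibly outside) that band.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Optional

from scipy import stats

from .calling import AlleleCall, CallLabel


def clopper_pearson(
    successes: int, trials: int, conf: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval, returned in percent.

    Lower bound is 0 when ``successes`` = 0 and upper bound 100 when
    ``successes`` = ``trials``; otherwise the bounds are beta-distribution
    quantiles.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - conf
    if successes == 0:
        low = 0.0
    else:
        low = float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    if successes == trials:
        high = 1.0
    else:
        high = float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return 100.0 * low, 100.0 * high


@dataclass(frozen=True)
class PerformanceSummary:
    tp: int
    fn: int
    tn: int
    fp: int
    conf: float = 0.95

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def concordant(self) -> int:
        return self.tp + self.tn

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return None if d == 0 else 100.0 * self.tp / d

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return None if d == 0 else 100.0 * self.tn / d

    @property
    def fnr(self) -> Optional[float]:
        s = self.sensitivity
        return None if s is None else 100.0 - s

    @property
    def fpr(self) -> Optional[float]:
        s = self.specificity
        return None if s is None else 100.0 - s

    @property
    def ci_sens(self) -> Optional[tuple[float, float]]:
        if self.tp + self.fn == 0:
            return None
        return clopper_pearson(self.tp, self.tp + self.fn, self.conf)

    @property
    def ci_spec(self) -> Optional[tuple[float, float]]:
        if self.tn + self.fp == 0:
            return None
        return clopper_pearson(self.tn, self.tn + self.fp, self.conf)

    @property
    def ci_fnr(self) -> Optional[tuple[float, float]]:
        ci = self.ci_sens
        return None if ci is None else (100.0 - ci[1], 100.0 - ci[0])

    @property
    def ci_fpr(self) -> Optional[tuple[float, float]]:
        ci = self.ci_spec
        return None if ci is None else (100.0 - ci[1], 100.0 - ci[0])


def confusion_summary(calls: Iterable[AlleleCall]) -> PerformanceSummary:
    """Pool labelled calls into confusion counts (unlabelled calls rejected)."""
    counts = {CallLabel.TP: 0, CallLabel.FN: 0, CallLabel.TN: 0, CallLabel.FP: 0}
    for c in calls:
        if c.label is CallLabel.NO_TRUTH:
            raise ValueError(
                f"call at {c.site.key} has no truth label; "
                "run evaluate_vs_truth first or filter no-truth calls"
            )
        counts[c.label] += 1
    return PerformanceSummary(
        tp=counts[CallLabel.TP],
        fn=counts[CallLabel.FN],
        tn=counts[CallLabel.TN],
        fp=counts[CallLabel.FP],
    )


def summary_from_counts(tp: int, fn: int, tn: int, fp: int) -> PerformanceSummary:
    return PerformanceSummary(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class SpikeStats:
    """Summary of per-site minor-genotype fractions in one spike mixture."""

    n_sites: int
    mean: float
    sd: float
    median: float

    @property
    def mean_minus_1sd(self) -> float:
        return self.mean - self.sd

    @property
    def mean_plus_1sd(self) -> float:
        return self.mean + self.sd


def spike_statistics(minor_fractions: list[float]) -> SpikeStats:
    """Mean, sample SD, and median of per-site minor-genotype fractions (%)."""
    if len(minor_fractions) < 2:
        raise ValueError("spike statistics need >= 2 per-site fractions")
    return SpikeStats(
        n_sites=len(minor_fractions),
        mean=statistics.fmean(minor_fractions),
        sd=statistics.stdev(minor_fractions),
        median=statistics.median(minor_fractions),
    )


@dataclass(frozen=True)
class BandCheck:
    inside: bool
    distance: float  # 0 when inside; distance to the nearer band edge otherwise


def within_band(expected_fraction: float, spike: SpikeStats) -> BandCheck:
    """Is the expected minority fraction inside mean ± 1 SD (closed interval)?"""
    low, high = spike.mean_minus_1sd, spike.mean_plus_1sd
    if low <= expected_fraction <= high:
        return BandCheck(inside=True, distance=0.0)
    distance = min(abs(expected_fraction - low), abs(expected_fraction - high))
    return BandCheck(inside=False, distance=distance)
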