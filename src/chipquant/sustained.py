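"""Sustained-region identification and invariant-region normalization.

Regions of sustained high H3K27me3 enrichment — saturated marking that is
present across the whole cell population and therefore cannot increase
further — serve as the internal reference for quantitative cross-sample
comparison, playing the role a spike-in control would.  They are found with
a peak-centred 20-kb sliding-window scan: peak heights are dichotomized at
the per-sample 90th percentile, each window is tested for an excess of
positive peaks with a one-sided chi-square goodness-of-fit test, significant
windows are merged, and only regions significant in every condition are
kept.  Dividing each condition's cumulative AUC over those regions by the
smallest value yields per-sample scaling factors >= 1 that all peaks are
divided by.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import (
    CONDITIONS,
    ChipquantError,
    Condition,
    GenomicInterval,
    PeakSet,
    PipelineConfig,
    _chrom_sort_key,
)

__all__ = [
    "WindowTest",
    "NormalizationResult",
    "dichotomize",
    "window_chisq",
    "scan_windows",
    "merge_significant",
    "intersect_across_conditions",
    "cumulative_auc",
    "scaling_factors",
    "apply_scaling",
    "normalize_by_sustained_regions",
]


@dataclass(frozen=True)
class WindowTest:
    """One sliding-window enrichment test (window centred on a peak)."""

    window: GenomicInterval
    n_peaks: int
    n_positive: int
    chisq_stat: float
    p_value: float

    def __post_init__(self) -> None:
        if self.n_positive > self.n_peaks:
            raise ChipquantError("n_positive cannot exceed n_peaks")


@dataclass
class NormalizationResult:
    """Outcome of invariant-reference normalization for one mark."""

    sustained_regions: list[GenomicInterval]
    auc_by_condition: dict[Condition, float]
    scaling_factors: dict[Condition, float]
    normalized: dict[Condition, PeakSet]


def dichotomize(peaks: PeakSet, quantile: float = 0.90) -> np.ndarray:
    """Label each peak positive (True) iff its height exceeds the sample quantile.

    The cutoff is the linear-interpolation sample quantile of all max
    heights in this sample; the comparison is strict, so with the default
    0.90 roughly 10 % of peaks come out positive.
    """
    if len(peaks) < 10:
        raise ChipquantError(
            f"dichotomize needs at least 10 peaks for a stable quantile "
            f"(got {len(peaks)}); supply a larger peak track"
        )
    heights = peaks.heights()
    cutoff = float(np.quantile(heights, quantile, method="linear"))
    return heights > cutoff


def window_chisq(
    n_peaks: int, n_positive: int, genome_positive_fraction: float
) -> tuple[float, float]:
    """One-sided chi-square goodness-of-fit test for positive-peak excess.

    X^2 = (O+ - E+)^2/E+ + (O- - E-)^2/E- with E+ = n * pi.  Only
    enrichment can be significant: if the observed positive count does not
    exceed its expectation the p-value is 1.
    """
    if n_peaks <= 0:
        raise ChipquantError("window_chisq undefined for an empty window")
    pi = genome_positive_fraction
    if not 0.0 < pi < 1.0:
        raise ChipquantError("genome_positive_fraction must be in (0, 1)")
    if n_positive > n_peaks or n_positive < 0:
        raise ChipquantError("n_positive must be in [0, n_peaks]")
    e_pos = n_peaks * pi
    e_neg = n_peaks * (1.0 - pi)
    stat = (n_positive - e_pos) ** 2 / e_pos + (
        (n_peaks - n_positive) - e_neg
    ) ** 2 / e_neg
    if n_positive <= e_pos:
        return float(stat), 1.0
    return float(stat), float(math.erfc(math.sqrt(stat / 2.0)))


def scan_windows(
    peaks: PeakSet, labels: np.ndarray, window_size: int = 20_000
) -> list[WindowTest]:
    """Slide one window per peak (centred on its mean location) and test each.

    Window = [m - w/2, m + w/2); a peak belongs to every window its mean
    location falls in.  The expected positive fraction pi is the global
    positive fraction of this sample.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != len(peaks):
        raise ChipquantError("labels and peaks differ in length")
    pi = labels.mean()
    half = window_size // 2
    tests: list[WindowTest] = []
    # group by chromosome preserving the PeakSet index for labels
    chrom_idx: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        chrom_idx.setdefault(p.chrom, []).append(i)
    for chrom in sorted(chrom_idx, key=_chrom_sort_key):
        idx = np.array(chrom_idx[chrom], dtype=int)
        means = np.array([peaks.peaks[i].mean_location for i in idx], dtype=int)
        srt = np.argsort(means, kind="stable")
        means_s = means[srt]
        pos_s = labels[idx][srt].astype(int)
        cum = np.concatenate([[0], np.cumsum(pos_s)])
        lo = np.searchsorted(means_s, means_s - half, side="left")
        hi = np.searchsorted(means_s, means_s + half, side="left")
        n = hi - lo
        k = cum[hi] - cum[lo]
        for m, n_i, k_i in zip(means_s, n, k):
            start = m - half
            win = GenomicInterval(chrom, max(start, 0), m + half)
            if 0.0 < pi < 1.0:
                stat, p = window_chisq(int(n_i), int(k_i), pi)
            else:
                # degenerate dichotomization: no informative test possible
                stat, p = 0.0, 1.0
            tests.append(WindowTest(win, int(n_i), int(k_i), stat, p))
    return tests


def _merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals; overlapping or book-ended intervals are merged."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def merge_significant(
    tests: Sequence[WindowTest], p_threshold: float = 1e-5
) -> list[GenomicInterval]:
    """Union all windows with p < threshold into maximal regions."""
    sig = [t.window for t in tests if t.p_value < p_threshold]
    if not sig:
        return []
    return _merge_intervals(sig)


def intersect_across_conditions(
    per_condition_regions: Mapping[Condition, Sequence[GenomicInterval]],
    min_fragment: int = 20_000,
) -> list[GenomicInterval]:
    """Base-pair intersection of the per-condition region sets.

    Only genomic bases significant in every one of the four conditions
    survive; fragments shorter than ``min_fragment`` (one window by
    default) are discarded as slivers.  An empty intersection signals that
    the invariant-set assumption failed and normalization is impossible.
    """
    missing = [c.value for c in CONDITIONS if c not in per_condition_regions]
    if missing:
        raise ChipquantError(f"regions missing for condition(s) {missing}")

    def intersect_two(
        a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
    ) -> list[GenomicInterval]:
        out = []
        by_chrom_b: dict[str, list[GenomicInterval]] = {}
        for iv in b:
            by_chrom_b.setdefault(iv.chrom, []).append(iv)
        for iv in a:
            for other in by_chrom_b.get(iv.chrom, []):
                s = max(iv.start, other.start)
                e = min(iv.end, other.end)
                if s < e:
                    out.append(GenomicInterval(iv.chrom, s, e))
        return out

    result = list(per_condition_regions[CONDITIONS[0]])
    for cond in CONDITIONS[1:]:
        result = intersect_two(result, per_condition_regions[cond])
        if not result:
            break
    result = [iv for iv in _merge_intervals(result) if len(iv) >= min_fragment]
    if not result:
        raise ChipquantError(
            "no sustained regions shared by all conditions; cannot normalize "
            "(the invariant-set assumption does not hold for this dataset)"
        )
    return result


def cumulative_auc(
    peaks: PeakSet, regions: Sequence[GenomicInterval]
) -> float:
    """Sum of AUC over peaks whose mean location lies in any region."""
    total = 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    starts_ends = {
        c: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for c, ivs in by_chrom.items()
    }
    for p in peaks:
        se = starts_ends.get(p.chrom)
        if se is None:
            continue
        starts, ends = se
        j = np.searchsorted(starts, p.mean_location, side="right") - 1
        if j >= 0 and p.mean_location < ends[j]:
            total += p.auc
    return total


def scaling_factors(
    auc_by_condition: Mapping[Condition, float]
) -> dict[Condition, float]:
    """Divide each condition's cumulative AUC by the smallest one.

    The minimum factor is exactly 1.0; dividing the peaks by these factors
    shrinks the larger samples onto the smallest-AUC sample.
    """
    missing = [c.value for c in CONDITIONS if c not in auc_by_condition]
    if missing:
        raise ChipquantError(f"AUC missing for condition(s) {missing}")
    vals = {Condition.parse(c): float(v) for c, v in auc_by_condition.items()}
    if any(v <= 0 for v in vals.values()):
        raise ChipquantError("all cumulative AUC values must be positive")
    smallest = min(vals.values())
    return {c: v / smallest for c, v in vals.items()}


def apply_scaling(peaks: PeakSet, factor: float) -> PeakSet:
    """Divide every height and AUC by ``factor`` and record it.

    A PeakSet can be normalized exactly once; a second attempt is an error
    so that accidental double normalization is always detectable.
    """
    if peaks.scaling_factor_applied is not None:
        raise ChipquantError(
            f"PeakSet already normalized (factor {peaks.scaling_factor_applied}); "
            "refusing to scale twice"
        )
    if factor < 1.0:
        raise ChipquantError("scaling factor must be >= 1 (relative to smallest AUC)")
    return PeakSet(
        mark=peaks.mark,
        condition=peaks.condition,
        peaks=[p.scaled(factor) for p in peaks],
        scaling_factor_applied=factor,
    )


def normalize_by_sustained_regions(
    peaksets: Mapping[Condition, PeakSet],
    config: PipelineConfig | None = None,
) -> NormalizationResult:
    """Full invariant-region normalization of a four-condition mark.

    Runs the per-sample dichotomize/scan/merge chain, intersects the
    significant regions across all four conditions, derives AUC scaling
    factors over the shared regions and applies them.
    """
    config = config or PipelineConfig()
    missing = [c.value for c in CONDITIONS if c not in peaksets]
    if missing:
        raise ChipquantError(f"peak sets missing for condition(s) {missing}")
    per_condition: dict[Condition, list[GenomicInterval]] = {}
    for cond in CONDITIONS:
        ps = peaksets[cond]
        labels = dichotomize(ps, config.dichotomize_quantile)
        tests = scan_windows(ps, labels, config.window_size_bp)
        per_condition[cond] = merge_significant(tests, config.chisq_p_threshold)
    min_fragment = int(
        round(config.min_region_fraction_of_window * config.window_size_bp)
    )
    regions = intersect_across_conditions(per_condition, min_fragment)
    aucs = {c: cumulative_auc(peaksets[c], regions) for c in CONDITIONS}
    factors = scaling_factors(aucs)
    normalized = {c: apply_scaling(peaksets[c], factors[c]) for c in CONDITIONS}
    return NormalizationResult(
        sustained_regions=regions,
        auc_by_condition=aucs,
        scaling_factors=factors,
        normalized=normalized,
    )
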