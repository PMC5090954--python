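"""Shared fixtures: one default synthetic dataset and one full pipeline run.

The default dataset (seed 1) is generated once per session; the expensive
downstream products (both normalizations, the threshold report) are shared
by unit and acceptance tests alike.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from chipquant.invariant import normalize_by_invariant_genes
from chipquant.model import CONDITIONS, Condition, GenomicInterval, Mark, Peak, PeakSet
from chipquant.sustained import normalize_by_sustained_regions
from chipquant.synthetic import SyntheticConfig, generate_dataset
from chipquant.thresholds import build_threshold_report


def make_peak(chrom: str, start: int, width: int, height: float) -> Peak:
    """Rectangular peak helper used across test modules."""
    return Peak(
        GenomicInterval(chrom, start, start + width),
        start + width // 2,
        height,
        height * width,
    )


def peakset_from_heights(
    heights,
    spacing: int = 100_000,
    chrom: str = "chr1",
    mark: Mark = Mark.H3K27ME3,
    condition: Condition = Condition.T0,
    width: int = 500,
    normalized: bool = False,
) -> PeakSet:
    peaks = [
        make_peak(chrom, (i + 1) * spacing, width, float(h))
        for i, h in enumerate(heights)
    ]
    return PeakSet(
        mark=mark,
        condition=condition,
        peaks=peaks,
        scaling_factor_applied=1.0 if normalized else None,
    )


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SyntheticConfig(), seed=1)


@pytest.fixture(scope="session")
def pipeline(default_dataset):
    """Both normalizations plus the calibrated threshold on the default data."""
    ds = default_dataset
    k27_raw = {c: ds.peaksets[(Mark.H3K27ME3, c)] for c in CONDITIONS}
    k4_raw = {c: ds.peaksets[(Mark.H3K4ME3, c)] for c in CONDITIONS}
    k27 = normalize_by_sustained_regions(k27_raw)
    k4, invariant_ids = normalize_by_invariant_genes(
        k4_raw, ds.expression, ds.genes
    )
    report = build_threshold_report(
        k27.normalized,
        ds.peaksets[(Mark.REFERENCE, Condition.T0)],
        ds.genes,
        ds.expression,
    )
    return SimpleNamespace(
        dataset=ds,
        k27_raw=k27_raw,
        k4_raw=k4_raw,
        k27=k27,
        k4=k4,
        invariant_ids=invariant_ids,
        report=report,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20160901)
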