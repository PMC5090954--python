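"""Background-threshold calibration against a reference ChIP track.

After normalization, a single log2 peak-height cutoff is set for all
samples: the height above which the H3K27me3 signal correlates with an
independent reference ChIP (CBX8, an H3K27me3 reader, in the original
protocol).  Operationally this is the smallest cutoff on an ascending grid
whose per-gene-AUC Spearman correlation with the reference is significant
and within 95 % of the grid's maximum — peaks below it behave like noise,
peaks above it like signal the reference protein sees.  The biological
significance threshold is set at twice the background (one log2 unit
higher), and the calibration is validated against consistently highly
expressed genes, whose repressive-mark peaks must sit below background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .integrate import gene_auc_vector
from .model import (
    CONDITIONS,
    ChipquantError,
    Condition,
    ExpressionMatrix,
    GeneModel,
    PeakSet,
    PipelineConfig,
)
from .stats import spearman

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdReport",
    "calibrate_background",
    "biological_threshold",
    "highly_expressed_genes",
    "validate_threshold",
    "build_threshold_report",
]

#: default ascending grid of candidate log2 height cutoffs
DEFAULT_CUTOFF_GRID = tuple(np.arange(0.0, 6.01, 0.5))


@dataclass
class ThresholdReport:
    background_log2: float
    biological_log2: float
    reference_correlation_by_cutoff: dict[float, tuple[float, float]] = field(
        default_factory=dict
    )
    highly_expressed_gene_ids: set[str] = field(default_factory=set)
    median_k27_height_log2_in_high_expr: float | None = None
    validation_pass: bool | None = None


def calibrate_background(
    k27_t0: PeakSet,
    reference_t0: PeakSet | None,
    genes: Sequence[GeneModel],
    cutoff_grid: Sequence[float] = DEFAULT_CUTOFF_GRID,
    flank: int = 5000,
    alpha: float = 0.05,
    rho_fraction: float = 0.95,
) -> ThresholdReport:
    """Calibrate the background log2 height cutoff from a reference track.

    For each cutoff h on the ascending grid, per-gene H3K27me3 AUC
    restricted to peaks with log2(height) >= h is Spearman-correlated with
    the per-gene reference AUC; the background is the smallest h whose
    correlation is significant (p < alpha) and within ``rho_fraction`` of
    the grid's maximum rho.  The full rho/p trace is retained so the choice
    can be inspected or overridden.
    """
    if reference_t0 is None:
        raise ChipquantError(
            "no reference track supplied; pass an explicit background "
            "threshold (e.g. --background-log2) instead"
        )
    if not k27_t0.is_normalized:
        raise ChipquantError("calibrate_background requires normalized H3K27me3 peaks")
    grid = [float(h) for h in cutoff_grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ChipquantError("cutoff grid must be strictly ascending")
    ref_auc = gene_auc_vector(reference_t0, genes, flank=flank)
    trace: dict[float, tuple[float, float]] = {}
    for h in grid:
        obs = gene_auc_vector(k27_t0, genes, flank=flank, min_height_log2=h)
        try:
            res = spearman(obs, ref_auc)
            trace[h] = (res.statistic, res.p_value)
        except ChipquantError:
            # constant vector (e.g. cutoff above every peak): no correlation
            trace[h] = (float("nan"), 1.0)
    rhos = {h: r for h, (r, p) in trace.items() if not math.isnan(r)}
    sig = {h for h, (r, p) in trace.items() if p < alpha and not math.isnan(r)}
    if not sig:
        raise ChipquantError(
            "no cutoff achieves a significant correlation with the reference; "
            "cannot calibrate a background threshold"
        )
    max_rho = max(rhos[h] for h in sig)
    candidates = [h for h in grid if h in sig and rhos[h] >= rho_fraction * max_rho]
    background = min(candidates)
    return ThresholdReport(
        background_log2=background,
        biological_log2=float("nan"),
        reference_correlation_by_cutoff=trace,
    )


def biological_threshold(background_log2: float, offset: float = 1.0) -> float:
    """Biological-significance threshold: background + offset on log2 scale.

    The default offset of 1.0 log2 unit corresponds to twice the background
    level on linear scale.
    """
    return background_log2 + offset


def highly_expressed_genes(
    expr: ExpressionMatrix, percentile: float = 95.0
) -> set[str]:
    """Genes whose expression exceeds the per-array percentile on EVERY array."""
    cutoffs = np.percentile(expr.values, percentile, axis=0)
    mask = (expr.values > cutoffs[None, :]).all(axis=1)
    ids = {g for g, m in zip(expr.gene_ids, mask) if m}
    if not ids:
        logger.warning(
            "no gene exceeds the %.4g-th percentile on every array; "
            "threshold validation will be skipped",
            percentile,
        )
    return ids


def validate_threshold(
    k27: Mapping[Condition, PeakSet],
    high_expr: set[str],
    genes: Sequence[GeneModel],
    background_log2: float,
    flank: int = 5000,
) -> tuple[bool, float | None]:
    """Check that H3K27me3 in consistently highly expressed genes is noise.

    Pools the log2 max heights of all H3K27me3 peaks whose mean location
    falls in the gene region (gene span plus flanks) of any highly
    expressed gene, across all conditions, and passes iff their median lies
    below the background threshold.  Returns (pass, median_log2) — median
    is None when no peak falls in those genes (vacuous pass).
    """
    from .integrate import gene_region

    if not high_expr:
        raise ChipquantError("validate_threshold requires a non-empty gene set")
    target = [g for g in genes if g.gene_id in high_expr]
    regions: dict[str, list[tuple[int, int]]] = {}
    for g in target:
        iv = gene_region(g, flank)
        regions.setdefault(iv.chrom, []).append((iv.start, iv.end))
    heights: list[float] = []
    for cond in CONDITIONS:
        ps = k27.get(cond)
        if ps is None:
            continue
        for p in ps:
            for s, e in regions.get(p.chrom, ()):
                if s <= p.mean_location < e:
                    heights.append(math.log2(p.max_height))
                    break
    if not heights:
        logger.warning(
            "no H3K27me3 peaks in highly expressed genes; validation passes vacuously"
        )
        return True, None
    med = float(np.median(heights))
    return med < background_log2, med


def build_threshold_report(
    k27: Mapping[Condition, PeakSet],
    reference_t0: PeakSet | None,
    genes: Sequence[GeneModel],
    expr: ExpressionMatrix,
    config: PipelineConfig | None = None,
    cutoff_grid: Sequence[float] = DEFAULT_CUTOFF_GRID,
    background_log2: float | None = None,
) -> ThresholdReport:
    """Calibrate (or accept) the background threshold and validate it."""
    config = config or PipelineConfig()
    if background_log2 is None:
        report = calibrate_background(
            k27[Condition.T0],
            reference_t0,
            genes,
            cutoff_grid=cutoff_grid,
            flank=config.gene_flank_bp,
        )
    else:
        report = ThresholdReport(
            background_log2=float(background_log2), biological_log2=float("nan")
        )
    report.biological_log2 = biological_threshold(
        report.background_log2, config.biological_threshold_log2_offset
    )
    high = highly_expressed_genes(expr, config.high_expression_percentile)
    report.highly_expressed_gene_ids = high
    if high:
        ok, med = validate_threshold(
            k27, high, genes, report.background_log2, config.gene_flank_bp
        )
        report.validation_pass = ok
        report.median_k27_height_log2_in_high_expr = med
    return report
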