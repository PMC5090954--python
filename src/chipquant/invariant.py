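"""Invariant-gene normalization for H3K4me3.

Premise: genes whose transcription does not change across the oxygenation
time course should carry unchanged promoter H3K4me3.  Transcriptionally
invariant genes are selected from the expression matrix (coefficient of
variation < 0.10 over all arrays, expressed above background on every
array), the H3K4me3 AUC in a strand-aware window around each selected TSS
(-1000..+100 bp by default) is summed per condition, and scaling factors are
derived relative to the smallest sum exactly as for the sustained-region
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import (
    CONDITIONS,
    ChipquantError,
    Condition,
    ExpressionMatrix,
    GeneModel,
    PeakSet,
    PipelineConfig,
)
from .sustained import NormalizationResult, apply_scaling, scaling_factors

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCV",
    "compute_cv",
    "select_invariant",
    "tss_window_auc",
    "k4_scaling_factors",
    "normalize_by_invariant_genes",
]


@dataclass(frozen=True)
class GeneCV:
    gene_id: str
    mean_expr: float
    cv: float
    above_background: bool


def compute_cv(expr: ExpressionMatrix, ddof: int = 1) -> list[GeneCV]:
    """Per-gene coefficient of variation over all arrays.

    cv = sd / mean across every (condition, replicate) array; sample
    standard deviation (ddof = 1) by default.  A gene is above background
    iff its minimum expression over all arrays exceeds the matrix's
    background level.  Genes with non-positive mean have no defined CV and
    are excluded with a warning.
    """
    out: list[GeneCV] = []
    mins = expr.values.min(axis=1)
    means = expr.values.mean(axis=1)
    sds = expr.values.std(axis=1, ddof=ddof)
    for i, gene in enumerate(expr.gene_ids):
        if means[i] <= 0:
            logger.warning(
                "gene %s: non-positive mean expression (%.3g); CV undefined, excluded",
                gene,
                means[i],
            )
            continue
        out.append(
            GeneCV(
                gene_id=gene,
                mean_expr=float(means[i]),
                cv=float(sds[i] / means[i]),
                above_background=bool(mins[i] > expr.background_level),
            )
        )
    return out


def select_invariant(
    cvs: Sequence[GeneCV], cv_threshold: float = 0.10
) -> set[str]:
    """Genes with cv strictly below threshold and expressed above background."""
    selected = {g.gene_id for g in cvs if g.cv < cv_threshold and g.above_background}
    if not selected:
        raise ChipquantError(
            "no invariant genes (CV < threshold and above background); "
            "H3K4me3 normalization impossible"
        )
    return selected


def _tss_windows(
    genes: Sequence[GeneModel], window: tuple[int, int]
) -> dict[str, list[tuple[int, int]]]:
    """Strand-aware TSS windows as genomic intervals, upstream first."""
    upstream, downstream = window
    out: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - upstream, g.tss + downstream
        else:
            s, e = g.tss - downstream, g.tss + upstream
        out.setdefault(g.chrom, []).append((max(s, 0), e))
    return out


def tss_window_auc(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    window: tuple[int, int] = (1000, 100),
) -> float:
    """Sum of peak AUC over all TSS windows of the selected genes.

    A peak contributes iff its mean location lies in the union of windows,
    and contributes once even when windows overlap.
    """
    if not genes:
        raise ChipquantError("tss_window_auc requires a non-empty gene selection")
    windows = _tss_windows(genes, window)
    # merge per chromosome so a peak under overlapping windows counts once
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in windows.items():
        ivs = sorted(ivs)
        res = []
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                res.append((cs, ce))
                cs, ce = s, e
        res.append((cs, ce))
        merged[chrom] = (
            np.array([s for s, _ in res]),
            np.array([e for _, e in res]),
        )
    total = 0.0
    for p in peaks:
        se = merged.get(p.chrom)
        if se is None:
            continue
        starts, ends = se
        j = np.searchsorted(starts, p.mean_location, side="right") - 1
        if j >= 0 and p.mean_location < ends[j]:
            total += p.auc
    return total


# the scaling arithmetic is shared with the sustained-region stage
k4_scaling_factors = scaling_factors


def normalize_by_invariant_genes(
    peaksets: Mapping[Condition, PeakSet],
    expr: ExpressionMatrix,
    genes: Sequence[GeneModel],
    config: PipelineConfig | None = None,
) -> tuple[NormalizationResult, set[str]]:
    """Full invariant-gene normalization of a four-condition H3K4me3 set.

    Returns the normalization result (its ``sustained_regions`` slot is
    empty — the reference here is a gene set, not a region set) together
    with the set of selected invariant gene ids.
    """
    config = config or PipelineConfig()
    missing = [c.value for c in CONDITIONS if c not in peaksets]
    if missing:
        raise ChipquantError(f"peak sets missing for condition(s) {missing}")
    cvs = compute_cv(expr)
    invariant_ids = select_invariant(cvs, config.cv_threshold)
    selected = [g for g in genes if g.gene_id in invariant_ids]
    if not selected:
        raise ChipquantError(
            "invariant genes selected from expression are absent from the annotation"
        )
    aucs = {
        c: tss_window_auc(peaksets[c], selected, config.tss_window)
        for c in CONDITIONS
    }
    factors = k4_scaling_factors(aucs)
    normalized = {c: apply_scaling(peaksets[c], factors[c]) for c in CONDITIONS}
    result = NormalizationResult(
        sustained_regions=[],
        auc_by_condition=aucs,
        scaling_factors=factors,
        normalized=normalized,
    )
    return result, invariant_ids
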