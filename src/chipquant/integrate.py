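"""Gene-level integration of normalized peak data with the transcriptome.

A gene region is the span from the 5'-most TSS to the 3' end of the last
exon plus 5-kb regulatory flanks.  A gene is *marked* by a histone
modification when at least one peak above the background threshold lies in
its region; its enrichment level is the total AUC of *all* member peaks
(sub-threshold peaks included) — the two rules are deliberately
independent.  Genes marked by both H3K4me3 and H3K27me3 in the same
condition are *bivalent*.  Promoters are classified into high /
intermediate / low CpG-content classes (HCP / ICP / LCP) by the classic
CpG observed/expected-ratio criteria on 500-bp sliding windows over
-700..+200 around the TSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .model import (
    CONDITIONS,
    ChipquantError,
    Condition,
    GeneModel,
    GenomicInterval,
    Mark,
    PeakSet,
)
from .stats import TestResult, spearman, wilcoxon_signed_rank

__all__ = [
    "GeneEnrichment",
    "BivalencyCall",
    "CpGClassCounts",
    "gene_region",
    "gene_auc_vector",
    "call_marked",
    "call_bivalent",
    "enrichment_dynamics",
    "classify_promoter_cpg",
    "cpg_state_table",
    "reference_set_overlap",
    "sample_correlation",
]

BIVALENCY_STATES = ("none", "K4_only", "K27_only", "bivalent")


@dataclass(frozen=True)
class GeneEnrichment:
    gene_id: str
    condition: Condition
    mark: Mark
    total_auc: float
    log2_auc: float | None  # None when total_auc == 0 (reported as missing)
    marked: bool


@dataclass(frozen=True)
class BivalencyCall:
    gene_id: str
    condition: Condition
    state: str

    def __post_init__(self) -> None:
        if self.state not in BIVALENCY_STATES:
            raise ChipquantError(f"invalid bivalency state {self.state!r}")


@dataclass
class CpGClassCounts:
    """Per-CpG-class counts of K4-marked, K27-marked and bivalent promoters."""

    totals: dict[str, int]
    k4_marked: dict[str, int]
    k27_marked: dict[str, int]
    bivalent: dict[str, int]

    def percentages(self, which: str) -> dict[str, float | None]:
        counts = getattr(self, which)
        return {
            cls: (100.0 * counts[cls] / self.totals[cls]) if self.totals[cls] else None
            for cls in self.totals
        }


def gene_region(gene: GeneModel, flank: int = 5000) -> GenomicInterval:
    """Gene span (5' TSS to 3' end) plus regulatory flanks, clipped at zero."""
    return GenomicInterval(
        gene.chrom, max(gene.left - flank, 0), gene.right + flank
    )


def _assign_peaks(
    peaks: PeakSet, genes: Sequence[GeneModel], flank: int
) -> dict[str, list[int]]:
    """Map gene_id -> indices of peaks whose mean location is in its region.

    A peak lying in two overlapping gene regions is counted for both genes.
    """
    regions: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        iv = gene_region(g, flank)
        regions.setdefault(g.chrom, []).append((iv.start, iv.end, g.gene_id))
    out: dict[str, list[int]] = {g.gene_id: [] for g in genes}
    for chrom, regs in regions.items():
        regs.sort()
        starts = np.array([r[0] for r in regs])
        max_len = max(r[1] - r[0] for r in regs)
        idx_peaks = [
            (i, p.mean_location) for i, p in enumerate(peaks) if p.chrom == chrom
        ]
        for i, m in idx_peaks:
            # candidate genes start within max_len left of the peak
            j = int(np.searchsorted(starts, m, side="right"))
            k = j - 1
            while k >= 0 and regs[k][0] > m - max_len:
                if regs[k][0] <= m < regs[k][1]:
                    out[regs[k][2]].append(i)
                k -= 1
    return out


def gene_auc_vector(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    flank: int = 5000,
    min_height_log2: float | None = None,
) -> np.ndarray:
    """Per-gene total AUC, optionally restricted to peaks above a log2 height."""
    assign = _assign_peaks(peaks, genes, flank)
    aucs = peaks.aucs()
    if min_height_log2 is not None:
        heights = peaks.heights()
        keep = heights >= 2.0**min_height_log2
    else:
        keep = np.ones(len(aucs), dtype=bool)
    out = np.zeros(len(genes))
    for gi, g in enumerate(genes):
        idx = assign[g.gene_id]
        if idx:
            ix = np.array(idx, dtype=int)
            out[gi] = aucs[ix][keep[ix]].sum()
    return out


def call_marked(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    background_log2: float,
    flank: int = 5000,
) -> dict[str, GeneEnrichment]:
    """Per-gene enrichment and marked status for one mark in one condition.

    marked: at least one member peak with log2(height) >= background.
    total_auc: AUC summed over ALL member peaks, marked or not.
    """
    if not peaks.is_normalized:
        raise ChipquantError(
            "call_marked requires normalized peaks (no scaling factor recorded)"
        )
    assign = _assign_peaks(peaks, genes, flank)
    aucs = peaks.aucs()
    heights = peaks.heights()
    supra = heights >= 2.0**background_log2
    out: dict[str, GeneEnrichment] = {}
    for g in genes:
        idx = np.array(assign[g.gene_id], dtype=int)
        total = float(aucs[idx].sum()) if len(idx) else 0.0
        marked = bool(supra[idx].any()) if len(idx) else False
        out[g.gene_id] = GeneEnrichment(
            gene_id=g.gene_id,
            condition=peaks.condition,
            mark=peaks.mark,
            total_auc=total,
            log2_auc=math.log2(total) if total > 0 else None,
            marked=marked,
        )
    return out


def call_bivalent(
    k4_enrichment: Mapping[str, GeneEnrichment],
    k27_enrichment: Mapping[str, GeneEnrichment],
) -> dict[str, BivalencyCall]:
    """Combine the two marked flags into the four-state bivalency call."""
    if set(k4_enrichment) != set(k27_enrichment):
        raise ChipquantError("bivalency requires identical gene universes per mark")
    out: dict[str, BivalencyCall] = {}
    for gene_id, k4 in k4_enrichment.items():
        k27 = k27_enrichment[gene_id]
        if k4.condition != k27.condition:
            raise ChipquantError("bivalency requires calls from the same condition")
        if k4.marked and k27.marked:
            state = "bivalent"
        elif k4.marked:
            state = "K4_only"
        elif k27.marked:
            state = "K27_only"
        else:
            state = "none"
        out[gene_id] = BivalencyCall(gene_id, k4.condition, state)
    return out


@dataclass(frozen=True)
class ConditionDynamics:
    condition: Condition
    n_genes: int
    mean_log2_auc: float
    se_log2_auc: float
    fold_change_vs_t0: float
    wilcoxon_p_vs_t0: float


def enrichment_dynamics(
    per_condition: Mapping[Condition, Mapping[str, GeneEnrichment]],
) -> dict[Condition, ConditionDynamics]:
    """Mean log2 gene AUC, fold change vs t0 and Wilcoxon p per condition.

    Each non-reference condition is compared to t0 on the genes with
    nonzero AUC in both conditions (paired); the fold change is
    2 ** (mean log2 AUC difference), i.e. the ratio of geometric means.
    """
    if Condition.T0 not in per_condition:
        raise ChipquantError("enrichment dynamics requires the t0 reference condition")
    base = per_condition[Condition.T0]
    out: dict[Condition, ConditionDynamics] = {}
    for cond, table in per_condition.items():
        paired = [
            g
            for g in table
            if table[g].total_auc > 0 and g in base and base[g].total_auc > 0
        ]
        if len(paired) < 2:
            raise ChipquantError(
                f"fewer than 2 genes with nonzero AUC paired between t0 and {cond}"
            )
        cur = np.array([math.log2(table[g].total_auc) for g in paired])
        ref = np.array([math.log2(base[g].total_auc) for g in paired])
        diff_mean = float(cur.mean() - ref.mean())
        if cond == Condition.T0:
            p = 1.0
        else:
            try:
                p = wilcoxon_signed_rank(cur, ref).p_value
            except ChipquantError:
                # all paired differences zero: no evidence of change
                p = 1.0
        out[cond] = ConditionDynamics(
            condition=cond,
            n_genes=len(paired),
            mean_log2_auc=float(cur.mean()),
            se_log2_auc=float(cur.std(ddof=1) / math.sqrt(len(cur))),
            fold_change_vs_t0=2.0**diff_mean,
            wilcoxon_p_vs_t0=p,
        )
    return out


def classify_promoter_cpg(
    promoter_sequence: str,
    tss_offset: int | None = None,
    window: int = 500,
    hcp_ratio: float = 0.75,
    lcp_ratio: float = 0.48,
    hcp_gc: float = 0.55,
    max_n_fraction: float = 0.10,
) -> str:
    """Classify a promoter as HCP / ICP / LCP by CpG content.

    Scans all 500-bp windows of the promoter region — canonically
    -700..+200 around the TSS; pass ``tss_offset`` (the TSS index within
    the sequence) to trim a longer sequence to that region.  Per window,
    CpG ratio = (#CpG * L) / (#C * #G) and GC fraction = (#C + #G) / L.
    HCP: some window with ratio > 0.75 and GC > 0.55; LCP: no window with
    ratio >= 0.48; ICP otherwise.  Sequences with more than 10 % N are
    unclassifiable ('unknown').
    """
    seq = promoter_sequence.upper()
    if tss_offset is not None:
        start = tss_offset - 700
        end = tss_offset + 200
        if start < 0 or end > len(seq):
            raise ChipquantError(
                f"promoter sequence does not cover -700..+200 around the TSS "
                f"(length {len(seq)}, tss offset {tss_offset})"
            )
        seq = seq[start:end]
    if len(seq) < window:
        raise ChipquantError(
            f"promoter sequence shorter than the {window}-bp classification window"
        )
    if any(b not in "ACGTN" for b in seq):
        raise ChipquantError("promoter sequence contains non-ACGTN characters")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if (arr == ord("N")).mean() > max_n_fraction:
        return "unknown"
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(len(arr), dtype=np.int64)
    is_cg[:-1] = is_c[:-1] & is_g[1:]  # CpG starting at each position
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
    n_windows = len(arr) - window + 1
    starts = np.arange(n_windows)
    c = cum_c[starts + window] - cum_c[starts]
    g = cum_g[starts + window] - cum_g[starts]
    # CpG dinucleotides fully inside the window start at window positions 0..L-2
    cg = cum_cg[starts + window - 1] - cum_cg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((c > 0) & (g > 0), cg * window / (c * g), 0.0)
    gc = (c + g) / window
    if np.any((ratio > hcp_ratio) & (gc > hcp_gc)):
        return "HCP"
    if not np.any(ratio >= lcp_ratio):
        return "LCP"
    return "ICP"


def cpg_state_table(
    calls: Mapping[str, BivalencyCall],
    classes: Mapping[str, str],
) -> CpGClassCounts:
    """Count K4-marked, K27-marked and bivalent promoters per CpG class.

    Only genes with a known class are tabulated.  'Marked' for a mark means
    the gene carries that mark regardless of the other (so bivalent genes
    count in both marked columns and in the bivalent column).
    """
    known = {g: c for g, c in classes.items() if c in ("HCP", "ICP", "LCP")}
    if not known:
        raise ChipquantError("cpg_state_table requires at least one classified gene")
    cls_names = ("HCP", "ICP", "LCP")
    totals = {c: 0 for c in cls_names}
    k4 = {c: 0 for c in cls_names}
    k27 = {c: 0 for c in cls_names}
    biv = {c: 0 for c in cls_names}
    for gene_id, call in calls.items():
        cls = known.get(gene_id)
        if cls is None:
            continue
        totals[cls] += 1
        if call.state in ("K4_only", "bivalent"):
            k4[cls] += 1
        if call.state in ("K27_only", "bivalent"):
            k27[cls] += 1
        if call.state == "bivalent":
            biv[cls] += 1
    return CpGClassCounts(totals=totals, k4_marked=k4, k27_marked=k27, bivalent=biv)


@dataclass(frozen=True)
class OverlapResult:
    name: str
    overlap: int
    jaccard: float
    hypergeom_p: float


def reference_set_overlap(
    gene_set: set[str],
    reference_sets: Mapping[str, set[str]],
    universe: set[str],
) -> dict[str, OverlapResult]:
    """Overlap of a gene set with named reference lists on a stated universe.

    The hypergeometric tail p asks how surprising the observed overlap is
    when drawing |gene_set| genes from the universe.  Reference genes
    outside the universe are dropped (with an implicit warning when the
    whole list is disjoint from the universe).
    """
    import logging

    logger = logging.getLogger(__name__)
    if not universe:
        raise ChipquantError("reference_set_overlap requires an explicit gene universe")
    gene_set = gene_set & universe
    out: dict[str, OverlapResult] = {}
    for name, ref in reference_sets.items():
        ref_in = ref & universe
        if not ref_in:
            logger.warning(
                "reference set %s shares no genes with the universe", name
            )
            out[name] = OverlapResult(name, 0, 0.0, 1.0)
            continue
        k = len(gene_set & ref_in)
        union = len(gene_set | ref_in)
        p = float(
            hypergeom.sf(k - 1, len(universe), len(ref_in), len(gene_set))
        )
        out[name] = OverlapResult(
            name, k, k / union if union else 0.0, min(1.0, p)
        )
    return out


def sample_correlation(
    peaks_a: PeakSet, peaks_b: PeakSet, binning: int = 10_000
) -> TestResult:
    """Genome-wide Spearman correlation of two samples' binned AUC.

    The genome is tiled at ``binning`` bp, each sample's AUC is summed per
    bin (a peak contributes to the bin of its mean location), bins that are
    zero in both samples are excluded and the remainder is rank-correlated.
    """
    sums: dict[tuple[str, int], list[float]] = {}
    for which, ps in enumerate((peaks_a, peaks_b)):
        for p in ps:
            key = (p.chrom, p.mean_location // binning)
            if key not in sums:
                sums[key] = [0.0, 0.0]
            sums[key][which] += p.auc
    if len(sums) < 4:
        raise ChipquantError(
            "fewer than 4 genome bins carry signal; correlation undefined"
        )
    a = np.array([v[0] for v in sums.values()])
    b = np.array([v[1] for v in sums.values()])
    return spearman(a, b)
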