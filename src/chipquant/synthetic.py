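"""Synthetic four-condition ChIP-seq + expression datasets with planted truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be tested without any external download:

* a small multi-chromosome genome with non-overlapping genes, each with a
  promoter sequence synthesized to a target CpG class (HCP/ICP/LCP);
* intergenic *sustained regions* carrying saturated H3K27me3 — equal
  pre-distortion signal across conditions up to <= 1 % jitter — densely
  tiled with tall peaks so the sliding-window scan can find them;
* per-gene H3K4me3 TSS peaks and H3K27me3 gene-body peaks with log-normal
  heights, multiplied by planted per-gene fold changes (hypoxia-responsive
  genes) and a residual global drift solved so the mean log2 fold change
  over marked genes hits a configured target;
* low, narrow background peaks everywhere below a planted noise floor,
  plus a reference ChIP track (an H3K27me3-reader proxy) whose per-gene AUC
  tracks the true repressive signal — the handle for threshold calibration;
* a global per-condition scale distortion multiplying every height and AUC
  — exactly what the normalization must undo;
* a triplicate expression matrix in which planted invariant genes have
  tiny variation, hypoxia-responsive genes shift per condition and a
  fraction of genes sits below the background expression level.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io as cq_io
from .model import (
    CONDITIONS,
    ChipquantError,
    Condition,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Mark,
    Peak,
    PeakSet,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_genome",
    "generate_peaksets",
    "generate_expression",
    "generate_dataset",
    "write_dataset",
]

CPG_CLASSES = ("HCP", "ICP", "LCP")


def _default_scale_factors() -> dict[str, float]:
    return {"t0": 1.0, "t8": 1.5, "t24": 2.0, "t_plus8": 1.2}


def _default_cpg_fractions() -> dict[str, float]:
    return {"HCP": 0.50, "ICP": 0.30, "LCP": 0.20}


def _default_k4_mark_prob() -> dict[str, float]:
    # mirrors the strong preference of promoter H3K4me3 for CpG-rich classes
    return {"HCP": 0.75, "ICP": 0.58, "LCP": 0.13}


def _default_k27_mark_prob() -> dict[str, float]:
    # repressive marking is relatively enriched at CpG-poor promoters
    return {"HCP": 0.10, "ICP": 0.10, "LCP": 0.25}


def _default_bivalent_prob() -> dict[str, float]:
    # bivalency concentrates at CpG-rich (developmental) promoters
    return {"HCP": 0.10, "ICP": 0.06, "LCP": 0.03}


def _default_k4_global() -> dict[str, float]:
    # target mean log2 fold change over K4-marked genes per condition
    return {"t8": 0.91, "t24": 1.21, "t_plus8": 0.59}


def _default_k27_global() -> dict[str, float]:
    return {"t8": 0.86, "t24": 0.52, "t_plus8": 0.11}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the study conditions."""

    # genome geometry
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (1500, 5000)
    gene_min_gap: int = 10_000
    cpg_fractions: dict[str, float] = field(default_factory=_default_cpg_fractions)
    promoter_upstream: int = 700
    promoter_downstream: int = 200
    # sustained H3K27me3 regions
    n_sustained_regions: int = 4
    sustained_region_length: int = 200_000
    sustained_peak_spacing: int = 2000
    sustained_peak_height: float = 90.0
    sustained_height_sigma: float = 0.15
    sustained_jitter: float = 0.01
    # planted per-condition scale distortion (what normalization must undo)
    scale_factors: dict[str, float] = field(default_factory=_default_scale_factors)
    # gene roles
    frac_invariant: float = 0.15
    frac_high_expr: float = 0.03
    frac_low_expr: float = 0.15
    frac_dynamic: float = 0.15
    k4_mark_prob: dict[str, float] = field(default_factory=_default_k4_mark_prob)
    k27_mark_prob: dict[str, float] = field(default_factory=_default_k27_mark_prob)
    bivalent_prob: dict[str, float] = field(default_factory=_default_bivalent_prob)
    dynamic_fc_range: tuple[float, float] = (1.5, 4.0)
    global_k4_log2fc: dict[str, float] = field(default_factory=_default_k4_global)
    global_k27_log2fc: dict[str, float] = field(default_factory=_default_k27_global)
    # peak model (heights linear; log-normal with natural-log sigma)
    signal_min_log2: float = 3.4
    k4_height_log2_median: float = 4.5
    k27_height_log2_median: float = 4.0
    peak_height_sigma: float = 0.5
    condition_jitter: float = 0.05
    reference_noise_sigma: float = 0.25
    # background noise peaks (the planted noise floor)
    noise_floor_log2: float = 2.9
    noise_min_log2: float = 1.5
    noise_density_bp: int = 6000
    # expression model (log2 scale)
    expression_background: float = 5.0
    expression_noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ChipquantError("n_genes must be non-negative")
        if abs(sum(self.cpg_fractions.values()) - 1.0) > 1e-9:
            raise ChipquantError("cpg_fractions must sum to 1")
        missing = [c.value for c in CONDITIONS if c.value not in self.scale_factors]
        if missing:
            raise ChipquantError(f"scale_factors missing condition(s) {missing}")
        smallest = min(self.scale_factors.values())
        if smallest <= 0:
            raise ChipquantError("scale factors must be positive")
        # by construction the smallest planted factor is exactly 1.0
        self.scale_factors = {
            c: v / smallest for c, v in self.scale_factors.items()
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ChipquantError(
                f"unknown synthetic config key(s): {sorted(unknown)}"
            )
        data = dict(data)
        for key in ("gene_length_range", "dynamic_fc_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["dynamic_fc_range"] = list(self.dynamic_fc_range)
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth, the oracle for every downstream stage."""

    seed: int
    true_scale_factors: dict[Condition, float]
    sustained_regions: list[GenomicInterval]
    invariant_gene_ids: set[str]
    dynamic_gene_ids: dict[str, dict[Condition, float]]  # gene -> linear FC
    bivalent_gene_ids: set[str]
    cpg_class_by_gene: dict[str, str]
    high_expr_gene_ids: set[str] = field(default_factory=set)
    low_expr_gene_ids: set[str] = field(default_factory=set)
    k4_marked_ids: set[str] = field(default_factory=set)
    k27_marked_ids: set[str] = field(default_factory=set)
    # per-condition per-gene log2 fold change actually applied to each mark
    gene_k4_log2fc: dict[Condition, dict[str, float]] = field(default_factory=dict)
    gene_k27_log2fc: dict[Condition, dict[str, float]] = field(default_factory=dict)
    noise_floor_log2: float = 2.9
    signal_min_log2: float = 3.4


@dataclass
class SyntheticDataset:
    genes: list[GeneModel]
    promoters: dict[str, str]
    peaksets: dict[tuple[Mark, Condition], PeakSet]
    expression: ExpressionMatrix
    truth: SyntheticTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# genome + roles


_PROMOTER_PARAMS = {
    # class -> (GC content, CpG observed/expected target)
    "HCP": (0.65, 1.20),
    "ICP": (0.48, 0.65),
    "LCP": (0.40, 0.08),
}


def _synthesize_promoters(
    cls: str, n: int, length: int, rng: np.random.Generator
) -> list[str]:
    """Batch-generate promoter sequences with a first-order CpG Markov model.

    The chain has stationary-ish base composition at the target GC content;
    the C->G transition probability is scaled so the observed/expected CpG
    ratio lands near the class target.  Pattern-based, not evolutionary —
    just enough to exercise the classifier.
    """
    if n == 0:
        return []
    gc, ratio = _PROMOTER_PARAMS[cls]
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    trans = np.tile(p, (4, 1))
    p_g_after_c = min(ratio * p[2], 0.9)
    scale = (1.0 - p_g_after_c) / (1.0 - p[2])
    trans[1] = p * scale
    trans[1, 2] = p_g_after_c
    cum = trans.cumsum(axis=1)
    cum[:, -1] = 1.0
    states = np.empty((n, length), dtype=np.int8)
    states[:, 0] = rng.choice(4, size=n, p=p)
    u = rng.random((n, length))
    for j in range(1, length):
        states[:, j] = (u[:, j, None] > cum[states[:, j - 1]]).sum(axis=1)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bytes(alphabet[row]).decode() for row in states]


def _place_sustained_regions(config: SyntheticConfig, rng) -> list[GenomicInterval]:
    regions = []
    per_chrom: dict[int, int] = {}
    for i in range(config.n_sustained_regions):
        per_chrom[i % config.n_chroms] = per_chrom.get(i % config.n_chroms, 0) + 1
    for ci in range(config.n_chroms):
        k = per_chrom.get(ci, 0)
        if k == 0:
            continue
        chrom = f"chr{ci + 1}"
        length = config.sustained_region_length
        for j in range(k):
            anchor = int(config.chrom_length * (j + 1) / (k + 1))
            jitter = int(rng.integers(-50_000, 50_001))
            start = max(100_000, min(anchor + jitter, config.chrom_length - length - 100_000))
            regions.append(GenomicInterval(chrom, start, start + length))
    return sorted(regions)


def _free_intervals(
    chrom_length: int, blocked: list[GenomicInterval], buffer: int
) -> list[tuple[int, int]]:
    out = []
    pos = 0
    for iv in sorted(blocked, key=lambda v: v.start):
        s = max(0, iv.start - buffer)
        if s > pos:
            out.append((pos, s))
        pos = max(pos, iv.end + buffer)
    if pos < chrom_length:
        out.append((pos, chrom_length))
    return out


def generate_genome(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[list[GeneModel], dict[str, str], SyntheticTruth]:
    """Generate the annotation, promoter sequences and truth skeleton.

    Genes are placed uniformly on the free (non-sustained-region) genome
    with a minimum inter-gene gap; CpG classes, mark assignments, gene
    roles (invariant / highly expressed / low-expressed / dynamic) and the
    per-gene, per-condition log2 fold changes for both marks are all drawn
    here so that the peak and expression generators stay consistent.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    regions = _place_sustained_regions(config, rng)
    factors = {Condition.parse(c): float(v) for c, v in config.scale_factors.items()}
    truth = SyntheticTruth(
        seed=seed,
        true_scale_factors=factors,
        sustained_regions=regions,
        invariant_gene_ids=set(),
        dynamic_gene_ids={},
        bivalent_gene_ids=set(),
        cpg_class_by_gene={},
        noise_floor_log2=config.noise_floor_log2,
        signal_min_log2=config.signal_min_log2,
    )
    if config.n_genes == 0:
        for cond in CONDITIONS:
            truth.gene_k4_log2fc[cond] = {}
            truth.gene_k27_log2fc[cond] = {}
        return [], {}, truth

    # --- placement ---------------------------------------------------------
    buffer = 2 * config.gene_min_gap
    free: list[tuple[str, int, int]] = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        blocked = [r for r in regions if r.chrom == chrom]
        for s, e in _free_intervals(config.chrom_length, blocked, buffer):
            free.append((chrom, s, e))
    total_free = sum(e - s for _, s, e in free)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    # allocate genes to free intervals proportionally to their length
    alloc = [int(config.n_genes * (e - s) / total_free) for _, s, e in free]
    i = 0
    while sum(alloc) < config.n_genes:
        alloc[i % len(alloc)] += 1
        i += 1
    genes: list[GeneModel] = []
    gi = 0
    for (chrom, s, e), k in zip(free, alloc):
        if k == 0:
            continue
        seg_lengths = lengths[gi : gi + k]
        required = int(seg_lengths.sum()) + (k + 1) * config.gene_min_gap
        slack = (e - s) - required
        if slack < 0:
            raise ChipquantError(
                "genes do not fit on the genome with the requested gap; "
                "increase chrom_length or reduce n_genes"
            )
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = s
        for j in range(k):
            pos += config.gene_min_gap + int(extra[j])
            length = int(seg_lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            left, right = pos, pos + length
            gene_id = f"G{gi + j + 1:05d}"
            if strand == "+":
                genes.append(GeneModel(gene_id, chrom, "+", left, right))
            else:
                genes.append(GeneModel(gene_id, chrom, "-", right, left))
            pos = right
        gi += k
    if len(genes) != config.n_genes:  # pragma: no cover - defensive
        raise ChipquantError("gene placement lost genes; this is a bug")

    # --- CpG classes and promoters ----------------------------------------
    n = len(genes)
    class_counts = {
        c: int(round(f * n)) for c, f in config.cpg_fractions.items()
    }
    while sum(class_counts.values()) < n:
        class_counts["HCP"] += 1
    while sum(class_counts.values()) > n:
        class_counts[max(class_counts, key=class_counts.get)] -= 1
    class_labels = np.array(
        sum(([c] * class_counts[c] for c in CPG_CLASSES), [])
    )
    rng.shuffle(class_labels)
    promoter_len = config.promoter_upstream + config.promoter_downstream
    promoters: dict[str, str] = {}
    for cls in CPG_CLASSES:
        idx = np.flatnonzero(class_labels == cls)
        seqs = _synthesize_promoters(cls, len(idx), promoter_len, rng)
        for j, s in zip(idx, seqs):
            promoters[genes[j].gene_id] = s
    classes = {g.gene_id: str(c) for g, c in zip(genes, class_labels)}
    genes = [
        dataclasses.replace(g, cpg_class=classes[g.gene_id]) for g in genes
    ]
    truth.cpg_class_by_gene = classes

    # --- marks -------------------------------------------------------------
    p_k4 = np.array([config.k4_mark_prob[classes[g.gene_id]] for g in genes])
    p_k27 = np.array([config.k27_mark_prob[classes[g.gene_id]] for g in genes])
    p_biv = np.array([config.bivalent_prob[classes[g.gene_id]] for g in genes])
    k4 = rng.random(n) < p_k4
    k27 = rng.random(n) < p_k27
    # bivalency is planted jointly (not as independent marks) so its
    # concentration at CpG-rich promoters is a property of the truth
    biv_draw = rng.random(n) < p_biv
    k4 |= biv_draw
    k27 |= biv_draw

    # --- roles -------------------------------------------------------------
    order = rng.permutation(n)
    n_inv = int(round(config.frac_invariant * n))
    n_high = int(round(config.frac_high_expr * n))
    n_low = int(round(config.frac_low_expr * n))
    n_dyn = int(round(config.frac_dynamic * n))
    inv_idx = order[:n_inv]
    high_idx = order[n_inv : n_inv + n_high]
    low_idx = order[n_inv + n_high : n_inv + n_high + n_low]
    rest = order[n_inv + n_high + n_low :]
    # anchors: invariant genes must carry (invariant) promoter H3K4me3;
    # consistently highly expressed genes carry H3K4me3 and no H3K27me3
    k4[inv_idx] = True
    k4[high_idx] = True
    k27[high_idx] = False
    k4[low_idx] = False  # unexpressed genes lack the active mark
    marked_rest = rest[k4[rest] | k27[rest]]
    dyn_idx = marked_rest[:n_dyn]

    ids = [str(g.gene_id) for g in genes]
    pick = lambda idx: {ids[int(i)] for i in idx}
    truth.invariant_gene_ids = pick(inv_idx)
    truth.high_expr_gene_ids = pick(high_idx)
    truth.low_expr_gene_ids = pick(low_idx)
    truth.k4_marked_ids = pick(np.flatnonzero(k4))
    truth.k27_marked_ids = pick(np.flatnonzero(k27))
    truth.bivalent_gene_ids = pick(np.flatnonzero(k4 & k27))

    # --- fold changes ------------------------------------------------------
    lo, hi = config.dynamic_fc_range
    base_fc = rng.uniform(lo, hi, len(dyn_idx))
    mult_t24 = rng.uniform(0.8, 1.4, len(dyn_idx))
    mult_p8 = rng.uniform(0.1, 0.5, len(dyn_idx))
    dyn_fc: dict[str, dict[Condition, float]] = {}
    for j, gidx in enumerate(dyn_idx):
        dyn_fc[ids[int(gidx)]] = {
            Condition.T0: 1.0,
            Condition.T8: float(base_fc[j]),
            Condition.T24: float(base_fc[j] ** mult_t24[j]),
            Condition.T_PLUS8: float(base_fc[j] ** mult_p8[j]),
        }
    truth.dynamic_gene_ids = dyn_fc

    anchors_k4 = pick(inv_idx) | pick(high_idx)
    global_targets = {
        Mark.H3K4ME3: config.global_k4_log2fc,
        Mark.H3K27ME3: config.global_k27_log2fc,
    }
    for mark, marked_mask in ((Mark.H3K4ME3, k4), (Mark.H3K27ME3, k27)):
        per_cond_store = (
            truth.gene_k4_log2fc if mark is Mark.H3K4ME3 else truth.gene_k27_log2fc
        )
        marked_ids = pick(np.flatnonzero(marked_mask))
        anchors = anchors_k4 if mark is Mark.H3K4ME3 else set()
        dynamic_in = [g for g in dyn_fc if g in marked_ids]
        residual = sorted(marked_ids - anchors - set(dynamic_in))
        for cond in CONDITIONS:
            target = global_targets[mark].get(cond.value, 0.0)
            dyn_sum = sum(np.log2(dyn_fc[g][cond]) for g in dynamic_in)
            if residual:
                m_log2 = (target * len(marked_ids) - dyn_sum) / len(residual)
            else:
                m_log2 = 0.0
            table = {}
            for g in sorted(marked_ids):
                if g in anchors:
                    table[g] = 0.0
                elif g in dyn_fc:
                    table[g] = float(np.log2(dyn_fc[g][cond]))
                else:
                    table[g] = float(m_log2)
            per_cond_store[cond] = table

    return genes, promoters, truth


# ---------------------------------------------------------------------------
# peaks


def _rect_peak(chrom: str, center: int, width: int, height: float) -> Peak:
    start = max(0, center - width // 2)
    return Peak(
        GenomicInterval(chrom, start, start + width),
        start + width // 2,
        float(height),
        float(height) * width,
    )


def _drop_overlapping(
    signal: list[Peak], noise: list[Peak]
) -> list[Peak]:
    """Keep noise peaks that overlap neither signal peaks nor each other."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in signal:
        by_chrom.setdefault(p.chrom, []).append((p.interval.start, p.interval.end))
    bounds = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        bounds[chrom] = (
            np.array([s for s, _ in ivs]),
            np.array([e for _, e in ivs]),
        )
    kept: list[Peak] = []
    last_end: dict[str, int] = {}
    for p in sorted(noise, key=lambda q: (q.chrom, q.interval.start)):
        s, e = p.interval.start, p.interval.end
        if p.chrom in bounds:
            starts, ends = bounds[p.chrom]
            j = np.searchsorted(starts, e, side="left") - 1
            if j >= 0 and ends[j] > s:
                continue
        if last_end.get(p.chrom, -1) >= s:
            continue
        kept.append(p)
        last_end[p.chrom] = e
    return kept


def _clipped_lognormal(
    rng, median_log2: float, sigma: float, min_log2: float, size: int
) -> np.ndarray:
    h = 2.0**median_log2 * np.exp(rng.normal(0.0, sigma, size))
    return np.maximum(h, 2.0**min_log2)


def generate_peaksets(
    genes: Sequence[GeneModel],
    truth: SyntheticTruth,
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> dict[tuple[Mark, Condition], PeakSet]:
    """Generate the eight mark/condition peak tracks plus the reference track.

    Per-gene base geometry and heights are drawn once and shared across
    conditions, so that before the planted scale distortion (a) sustained
    regions carry equal signal up to the configured jitter and (b) the only
    cross-condition differences at genes are the planted fold changes plus
    a small multiplicative jitter.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    factors = truth.true_scale_factors
    gene_by_id = {g.gene_id: g for g in genes}

    out: dict[tuple[Mark, Condition], PeakSet] = {}
    signal: dict[tuple[Mark, Condition], list[Peak]] = {
        (m, c): [] for m in (Mark.H3K4ME3, Mark.H3K27ME3) for c in CONDITIONS
    }
    reference: list[Peak] = []

    # --- sustained-region H3K27me3 ----------------------------------------
    for region in truth.sustained_regions:
        spacing = config.sustained_peak_spacing
        centers = np.arange(region.start + spacing // 2, region.end, spacing)
        centers = centers + rng.integers(-50, 51, len(centers))
        widths = rng.integers(400, 651, len(centers))
        h0 = config.sustained_peak_height * np.exp(
            rng.normal(0.0, config.sustained_height_sigma, len(centers))
        )
        jitter = rng.uniform(
            1.0 - config.sustained_jitter,
            1.0 + config.sustained_jitter,
            (len(CONDITIONS), len(centers)),
        )
        for ci, cond in enumerate(CONDITIONS):
            s = factors[cond]
            for c, w, h, j in zip(centers, widths, h0, jitter[ci]):
                signal[(Mark.H3K27ME3, cond)].append(
                    _rect_peak(region.chrom, int(c), int(w), h * j * s)
                )

    # --- gene peaks --------------------------------------------------------
    k4_ids = sorted(truth.k4_marked_ids)
    k27_ids = sorted(truth.k27_marked_ids)

    k4_h0 = _clipped_lognormal(
        rng,
        config.k4_height_log2_median,
        config.peak_height_sigma,
        config.signal_min_log2,
        len(k4_ids),
    )
    k4_w0 = rng.integers(300, 601, len(k4_ids))
    k4_centers = rng.integers(-250, 251, (len(CONDITIONS), len(k4_ids)))
    k4_jit = 1.0 + rng.normal(
        0.0, config.condition_jitter, (len(CONDITIONS), len(k4_ids))
    )
    for ci, cond in enumerate(CONDITIONS):
        fc = truth.gene_k4_log2fc.get(cond, {})
        s = factors[cond]
        for j, gid in enumerate(k4_ids):
            g = gene_by_id[gid]
            offset = 450 if g.strand == "-" else -450
            center = g.tss + offset + int(k4_centers[ci, j])
            h = k4_h0[j] * 2.0 ** fc.get(gid, 0.0) * k4_jit[ci, j] * s
            signal[(Mark.H3K4ME3, cond)].append(
                _rect_peak(g.chrom, center, int(k4_w0[j]), h)
            )

    n_body = 1 + (rng.random(len(k27_ids)) < 0.5).astype(int)
    k27_auc0: dict[str, float] = {}
    k27_geom: list[tuple[str, int, int, float]] = []  # gene, center, width, h0
    for j, gid in enumerate(k27_ids):
        g = gene_by_id[gid]
        span = g.right - g.left
        nb = int(n_body[j])
        seg = span // nb
        h0s = _clipped_lognormal(
            rng,
            config.k27_height_log2_median,
            config.peak_height_sigma,
            config.signal_min_log2,
            nb,
        )
        auc0 = 0.0
        for b in range(nb):
            width = int(min(600, max(200, seg - 150)))
            center = g.left + seg * b + seg // 2 + int(rng.integers(-50, 51))
            k27_geom.append((gid, center, width, float(h0s[b])))
            auc0 += float(h0s[b]) * width
        k27_auc0[gid] = auc0
    k27_jit = 1.0 + rng.normal(
        0.0, config.condition_jitter, (len(CONDITIONS), len(k27_geom))
    )
    for ci, cond in enumerate(CONDITIONS):
        fc = truth.gene_k27_log2fc.get(cond, {})
        s = factors[cond]
        for j, (gid, center, width, h0) in enumerate(k27_geom):
            g = gene_by_id[gid]
            h = h0 * 2.0 ** fc.get(gid, 0.0) * k27_jit[ci, j] * s
            signal[(Mark.H3K27ME3, cond)].append(
                _rect_peak(g.chrom, center, width, h)
            )

    # --- reference track (H3K27me3-reader proxy, t0 only) ------------------
    for gid in k27_ids:
        g = gene_by_id[gid]
        width = 500
        auc = k27_auc0[gid] * float(
            np.exp(rng.normal(0.0, config.reference_noise_sigma))
        )
        center = (g.left + g.right) // 2
        reference.append(_rect_peak(g.chrom, center, width, auc / width))

    # --- background noise below the planted floor --------------------------
    genome = [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)]
    total_len = sum(l for _, l in genome)
    n_noise = int(total_len // config.noise_density_bp)
    for mark in (Mark.H3K4ME3, Mark.H3K27ME3):
        for cond in CONDITIONS:
            pos = rng.integers(0, total_len, n_noise)
            widths = rng.integers(120, 251, n_noise)
            heights = 2.0 ** rng.uniform(
                config.noise_min_log2, config.noise_floor_log2, n_noise
            )
            noise = []
            for p, w, h in zip(pos, widths, heights):
                off = int(p)
                for chrom, length in genome:
                    if off < length:
                        if w // 2 < off < length - w:
                            noise.append(
                                _rect_peak(chrom, off, int(w), h * factors[cond])
                            )
                        break
                    off -= length
            peaks = signal[(mark, cond)]
            peaks.extend(_drop_overlapping(peaks, noise))

    for (mark, cond), peaks in signal.items():
        out[(mark, cond)] = PeakSet(mark=mark, condition=cond, peaks=peaks)
    out[(Mark.REFERENCE, Condition.T0)] = PeakSet(
        mark=Mark.REFERENCE, condition=Condition.T0, peaks=reference
    )
    return out


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    genes: Sequence[GeneModel],
    truth: SyntheticTruth,
    config: SyntheticConfig | None = None,
    seed: int = 0,
    n_replicates: int = 3,
) -> ExpressionMatrix:
    """Triplicate log2 expression per condition with planted variability.

    Invariant genes: high mean, tiny array noise (CV well below 0.05), no
    condition effect.  Dynamic genes: per-condition shifts of 1–2.5 log2
    units.  Stable background genes: a fixed spread of condition offsets
    sized to a per-gene target CV in 0.15–0.35 (so they are reliably above
    the invariance cutoff even in the zero-noise limit).  Low-expressed
    genes sit below the background level.  ``expression_noise_scale``
    scales only the array noise, not the condition structure.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    n = len(genes)
    labels = [(c, f"r{r + 1}") for c in CONDITIONS for r in range(n_replicates)]
    values = np.zeros((n, len(labels)))
    # spread of the fixed stable-gene offset pattern {±0.5, ±1.5}·s measured
    # as an (n-1)-denominator sd over 4 conditions x 3 replicates
    offset_sd_factor = float(np.sqrt(3 * 5.0 / 11.0))
    for i, g in enumerate(genes):
        gid = g.gene_id
        offsets = {c: 0.0 for c in CONDITIONS}
        if gid in truth.invariant_gene_ids:
            mean = rng.uniform(7.0, 11.0)
            sd = rng.uniform(0.01, 0.03) * mean
        elif gid in truth.high_expr_gene_ids:
            mean = rng.uniform(12.5, 13.5)
            sd = 0.15
        elif gid in truth.low_expr_gene_ids:
            mean = rng.uniform(2.5, 4.5)
            sd = 0.3
        elif gid in truth.dynamic_gene_ids:
            mean = rng.uniform(6.0, 10.0)
            sd = 0.25
            sign = 1.0 if rng.random() < 0.7 else -1.0
            # shift sized relative to the mean so responsive genes are
            # reliably outside the CV-based invariance selection
            shift = mean * rng.uniform(0.28, 0.5)
            offsets[Condition.T8] = sign * shift
            offsets[Condition.T24] = sign * shift * rng.uniform(0.8, 1.4)
            offsets[Condition.T_PLUS8] = sign * shift * rng.uniform(0.1, 0.5)
        else:
            mean = rng.uniform(5.5, 9.0)
            cv = rng.uniform(0.15, 0.35)
            s = cv * mean / offset_sd_factor
            pattern = np.array([-1.5, -0.5, 0.5, 1.5]) * s
            rng.shuffle(pattern)
            offsets = {c: float(p) for c, p in zip(CONDITIONS, pattern)}
            sd = 0.2
        for a, (cond, _) in enumerate(labels):
            noise = config.expression_noise_scale * rng.normal(0.0, sd)
            values[i, a] = mean + offsets[cond] + noise
    return ExpressionMatrix(
        gene_ids=[g.gene_id for g in genes],
        array_labels=labels,
        values=values,
        background_level=config.expression_background,
    )


# ---------------------------------------------------------------------------
# one-call dataset + disk serialization


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticDataset:
    """Generate genome, peaks and expression from one master seed."""
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    genes, promoters, truth = generate_genome(config, sub[0])
    truth.seed = seed
    peaksets = generate_peaksets(genes, truth, config, sub[1])
    expr = generate_expression(genes, truth, config, sub[2])
    return SyntheticDataset(genes, promoters, peaksets, expr, truth, config)


def truth_to_dict(truth: SyntheticTruth) -> dict:
    return {
        "seed": truth.seed,
        "true_scale_factors": {
            c.value: float(v) for c, v in truth.true_scale_factors.items()
        },
        "sustained_regions": [
            f"{r.chrom}:{r.start}-{r.end}" for r in truth.sustained_regions
        ],
        "invariant_gene_ids": sorted(truth.invariant_gene_ids),
        "dynamic_gene_ids": {
            g: {c.value: float(v) for c, v in fc.items()}
            for g, fc in sorted(truth.dynamic_gene_ids.items())
        },
        "bivalent_gene_ids": sorted(truth.bivalent_gene_ids),
        "cpg_class_by_gene": dict(sorted(truth.cpg_class_by_gene.items())),
        "high_expr_gene_ids": sorted(truth.high_expr_gene_ids),
        "low_expr_gene_ids": sorted(truth.low_expr_gene_ids),
        "k4_marked_ids": sorted(truth.k4_marked_ids),
        "k27_marked_ids": sorted(truth.k27_marked_ids),
        "noise_floor_log2": truth.noise_floor_log2,
        "signal_min_log2": truth.signal_min_log2,
    }


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the dataset as WIG/TSV/FASTA plus a YAML truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for (mark, cond), ps in sorted(
        dataset.peaksets.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        name = f"{mark.value}_{cond.value}.wig"
        cq_io.write_wig(ps, outdir / name)
        paths[f"wig:{mark.value}:{cond.value}"] = name
    cq_io.write_gene_annotation(dataset.genes, outdir / "annotation.tsv")
    paths["annotation"] = "annotation.tsv"
    cq_io.write_expression(dataset.expression, outdir / "expression.tsv")
    paths["expression"] = "expression.tsv"
    cq_io.write_fasta(dataset.promoters, outdir / "promoters.fasta")
    paths["promoters"] = "promoters.fasta"
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_to_dict(dataset.truth), fh, sort_keys=True)
    paths["truth"] = "truth.yaml"
    with open(outdir / "synthetic_config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    paths["config"] = "synthetic_config.yaml"
    return paths
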