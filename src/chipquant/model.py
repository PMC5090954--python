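"""Core domain types shared by every pipeline stage.

Coordinate convention
---------------------
All coordinates are 0-based, half-open internally.  WIG input is interpreted
as 1-based inclusive (UCSC convention) and converted on read; BED output is
0-based half-open.  Peak signal values (heights, AUCs) are stored on a linear
scale throughout; log2 is applied only at thresholding and in reports.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Condition",
    "CONDITIONS",
    "Mark",
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "ExpressionMatrix",
    "PipelineConfig",
    "ChipquantError",
]


class ChipquantError(Exception):
    """Base class for all pipeline errors."""


class Condition(str, enum.Enum):
    """Experimental condition label.

    The four states of the oxygenation time course: normoxia (t0), 8 h of
    hypoxia (t8), 24 h of hypoxia (t24) and 8 h of reoxygenation (t_plus8).
    """

    T0 = "t0"
    T8 = "t8"
    T24 = "t24"
    T_PLUS8 = "t_plus8"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, value: "str | Condition") -> "Condition":
        if isinstance(value, Condition):
            return value
        try:
            return cls(value)
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise ChipquantError(
                f"unknown condition label {value!r}; expected one of {valid}"
            ) from None


#: Canonical condition order used in every report.
CONDITIONS: tuple[Condition, ...] = (
    Condition.T0,
    Condition.T8,
    Condition.T24,
    Condition.T_PLUS8,
)


class Mark(str, enum.Enum):
    """Histone mark (or reference ChIP) a peak track was called from."""

    H3K4ME3 = "H3K4me3"
    H3K27ME3 = "H3K27me3"
    REFERENCE = "reference"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, value: "str | Mark") -> "Mark":
        if isinstance(value, Mark):
            return value
        try:
            return cls(value)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ChipquantError(
                f"unknown mark {value!r}; expected one of {valid}"
            ) from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ChipquantError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ChipquantError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end} (start must be < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.intersection_length(other)
        union = len(self) + len(other) - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class Peak:
    """A called enrichment interval summarized by location, height and AUC.

    ``mean_location`` is the signal-weighted mean base position (the peak's
    centre of mass), ``max_height`` the maximum per-base value and ``auc``
    the per-base values summed over the footprint, all on linear scale.
    """

    interval: GenomicInterval
    mean_location: int
    max_height: float
    auc: float

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.mean_location < self.interval.end):
            raise ChipquantError(
                f"mean_location {self.mean_location} outside "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if not self.max_height > 0:
            raise ChipquantError("max_height must be positive")
        if self.auc < 0:
            raise ChipquantError("auc must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def scaled(self, factor: float) -> "Peak":
        """Return a copy with height and AUC divided by ``factor``."""
        return replace(self, max_height=self.max_height / factor, auc=self.auc / factor)


def _chrom_sort_key(chrom: str):
    # natural ordering so chr2 < chr10
    digits = "".join(c for c in chrom if c.isdigit())
    return (chrom.rstrip("0123456789"), int(digits) if digits else -1)


@dataclass
class PeakSet:
    """All peaks of one mark in one sample/condition.

    ``scaling_factor_applied`` records the (single) normalization divisor
    applied to every height and AUC; it is ``None`` for raw data, and any
    second normalization attempt is rejected so that double scaling is
    detectable.
    """

    mark: Mark
    condition: Condition
    peaks: list[Peak] = field(default_factory=list)
    scaling_factor_applied: float | None = None

    def __post_init__(self) -> None:
        self.mark = Mark.parse(self.mark)
        self.condition = Condition.parse(self.condition)
        self.peaks = sorted(
            self.peaks, key=lambda p: (_chrom_sort_key(p.chrom), p.interval.start)
        )
        if self.scaling_factor_applied is not None and self.scaling_factor_applied <= 0:
            raise ChipquantError("scaling factor must be positive")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def is_normalized(self) -> bool:
        return self.scaling_factor_applied is not None

    def heights(self) -> np.ndarray:
        return np.array([p.max_height for p in self.peaks], dtype=float)

    def aucs(self) -> np.ndarray:
        return np.array([p.auc for p in self.peaks], dtype=float)

    def chroms(self) -> list[str]:
        return sorted({p.chrom for p in self.peaks}, key=_chrom_sort_key)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what gene-level integration needs.

    ``tss`` is the biological 5' position (most upstream TSS) and ``end3``
    the 3' end of the last exon; on the minus strand tss > end3.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    end3: int
    cpg_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ChipquantError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss == self.end3:
            raise ChipquantError(f"gene {self.gene_id}: tss == end3 ({self.tss})")
        if self.strand == "+" and not self.tss < self.end3:
            raise ChipquantError(
                f"gene {self.gene_id}: + strand requires tss < end3"
            )
        if self.strand == "-" and not self.tss > self.end3:
            raise ChipquantError(
                f"gene {self.gene_id}: - strand requires tss > end3"
            )
        if self.cpg_class not in ("HCP", "ICP", "LCP", "unknown"):
            raise ChipquantError(
                f"gene {self.gene_id}: invalid cpg_class {self.cpg_class!r}"
            )

    @property
    def left(self) -> int:
        return min(self.tss, self.end3)

    @property
    def right(self) -> int:
        return max(self.tss, self.end3)


class ExpressionMatrix:
    """Normalized (log-scale) expression values, genes x arrays.

    Array labels are (condition, replicate) pairs; all four conditions must
    be present and every pair must be unique.  ``background_level`` is the
    expression floor below which a gene is not considered expressed.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        array_labels: Sequence[tuple[Condition, str]],
        values: np.ndarray,
        background_level: float,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(array_labels)):
            raise ChipquantError(
                f"expression matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(array_labels)} arrays"
            )
        if np.isnan(values).any():
            raise ChipquantError("expression matrix contains missing values")
        if len(set(gene_ids)) != len(gene_ids):
            raise ChipquantError("duplicate gene ids in expression matrix")
        labels = [(Condition.parse(c), str(r)) for c, r in array_labels]
        if len(set(labels)) != len(labels):
            raise ChipquantError("duplicate (condition, replicate) array labels")
        present = {c for c, _ in labels}
        missing = [c.value for c in CONDITIONS if c not in present]
        if missing:
            found = sorted(c.value for c in present)
            raise ChipquantError(
                f"expression matrix missing condition(s) {missing}; found {found}"
            )
        self.gene_ids = list(gene_ids)
        self.array_labels = labels
        self.values = values
        self.background_level = float(background_level)
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_labels)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index[gene_id]]

    def condition_columns(self, condition: Condition) -> np.ndarray:
        condition = Condition.parse(condition)
        cols = [i for i, (c, _) in enumerate(self.array_labels) if c == condition]
        return np.array(cols, dtype=int)

    def to_frame(self):
        import pandas as pd

        cols = [f"{c.value}_{r}" for c, r in self.array_labels]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with the published defaults.

    window_size_bp
        sliding-window width of the enrichment scan (20 kb).
    dichotomize_quantile
        per-sample peak-height quantile separating positive from negative
        peaks (0.90, i.e. the 90th percentile).
    chisq_p_threshold
        raw (uncorrected) p-value cutoff for a significant window (1e-5).
    cv_threshold
        coefficient-of-variation cutoff selecting transcriptionally
        invariant genes (0.10).
    tss_window
        (upstream, downstream) extent of the TSS window used for the
        H3K4me3 normalization sum, in bp ((1000, 100), i.e. -1000..+100).
    gene_flank_bp
        regulatory flank added up- and downstream of the gene span (5 kb).
    high_expression_percentile
        per-array expression percentile a gene must exceed on every array
        to count as consistently highly expressed (95).
    biological_threshold_log2_offset
        log2 offset between the background and the biological-significance
        threshold (1.0, i.e. two-fold on linear scale).
    min_region_fraction_of_window
        sustained-region fragments shorter than this fraction of the window
        are discarded after the cross-condition intersection (1.0).
    correlation_bin_bp
        genome bin size for whole-sample correlation (10 kb).
    """

    window_size_bp: int = 20_000
    dichotomize_quantile: float = 0.90
    chisq_p_threshold: float = 1e-5
    cv_threshold: float = 0.10
    tss_window: tuple[int, int] = (1000, 100)
    gene_flank_bp: int = 5000
    high_expression_percentile: float = 95.0
    biological_threshold_log2_offset: float = 1.0
    min_region_fraction_of_window: float = 1.0
    correlation_bin_bp: int = 10_000
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dichotomize_quantile < 1:
            raise ChipquantError("dichotomize_quantile must be in (0, 1)")
        if self.window_size_bp <= 0:
            raise ChipquantError("window_size_bp must be positive")
        if not 0 < self.chisq_p_threshold < 1:
            raise ChipquantError("chisq_p_threshold must be in (0, 1)")
        up, down = self.tss_window
        if up < 0 or down < 0:
            raise ChipquantError("tss_window extents must be non-negative")

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ChipquantError(
                f"unknown config key(s): {sorted(unknown)}; known keys: {sorted(known)}"
            )
        data = dict(data)
        if "tss_window" in data:
            data["tss_window"] = tuple(data["tss_window"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["tss_window"] = list(self.tss_window)
        return d


def log2_height(height: float) -> float:
    """Log2 of a linear peak height (reporting scale)."""
    return math.log2(height)


def check_same_genome(genes: Iterable[GeneModel]) -> None:
    """Reject duplicate gene ids in an annotation collection."""
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ChipquantError(f"duplicate gene id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)
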