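"""Readers and writers for the plain-text formats the pipeline touches.

WIG (variableStep / fixedStep, ``span`` supported) and bedGraph-style lines
are read into :class:`~chipquant.model.PeakSet` objects, treating every
maximal run of contiguous nonzero signal as one peak; the peak caller itself
is upstream of this package, so the WIG is assumed to contain only
called-peak signal.  All readers accept gzip-compressed input transparently.
"""

from __future__ import annotations

import gzip
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

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
    check_same_genome,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WigParseError",
    "read_wig",
    "write_wig",
    "write_bed",
    "read_bed_intervals",
    "write_bed3",
    "read_gene_annotation",
    "read_expression",
    "read_fasta",
    "write_fasta",
    "read_gene_list",
]


class WigParseError(ChipquantError):
    """Raised on malformed WIG input; the message names the offending line."""


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_kv(fields: Sequence[str], lineno: int) -> dict[str, str]:
    out = {}
    for f in fields:
        if "=" not in f:
            raise WigParseError(f"line {lineno}: malformed header field {f!r}")
        k, v = f.split("=", 1)
        out[k] = v
    return out


def _runs_to_peaks(chrom: str, segments: list[tuple[int, int, float]]) -> list[Peak]:
    peaks: list[Peak] = []
    run: list[tuple[int, int, float]] = []

    def flush() -> None:
        if not run:
            return
        start, end = run[0][0], run[-1][1]
        auc = 0.0
        max_h = 0.0
        pos_mass = 0.0  # relative to run start, to keep half-integers exact
        for s, e, v in run:
            n = e - s
            auc += v * n
            max_h = max(max_h, v)
            pos_mass += v * n * ((s - start) + (e - start) - 1) / 2.0
        # round-half-up; the tiny epsilon keeps exact .5 centers stable
        # against float summation error (offsets are bounded by run width)
        mean = start + int(math.floor(pos_mass / auc + 0.5 + 1e-9))
        mean = min(max(mean, start), end - 1)
        peaks.append(
            Peak(GenomicInterval(chrom, start, end), mean, max_h, auc)
        )
        run.clear()

    prev_end: int | None = None
    for s, e, v in segments:
        if prev_end is not None and s < prev_end:
            raise WigParseError(
                f"overlapping signal segments on {chrom} at position {s + 1}"
            )
        if v == 0.0 or (prev_end is not None and s > prev_end):
            flush()
        if v != 0.0:
            run.append((s, e, v))
        prev_end = e
    flush()
    return peaks


def read_wig(path, mark: Mark | str, condition: Condition | str) -> PeakSet:
    """Read a WIG (or bedGraph-line) peak track into a PeakSet.

    Contiguous runs of nonzero signal become peaks summarized by their
    signal-weighted mean location, maximum height and AUC (per-base sum).
    1-based inclusive WIG coordinates are converted to 0-based half-open.
    Chromosome blocks out of sorted order are reordered with a warning.
    """
    mark = Mark.parse(mark)
    condition = Condition.parse(condition)
    # per chrom: list of (start0, end0, value) in file order
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    chrom_order: list[str] = []

    mode: str | None = None  # "variable" | "fixed"
    cur_chrom: str | None = None
    span = 1
    fixed_pos = 0
    step = 1

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            head = fields[0]
            if head == "variableStep" or head == "fixedStep":
                kv = _parse_kv(fields[1:], lineno)
                if "chrom" not in kv:
                    raise WigParseError(f"line {lineno}: {head} without chrom=")
                cur_chrom = kv["chrom"]
                try:
                    span = int(kv.get("span", "1"))
                except ValueError:
                    raise WigParseError(f"line {lineno}: bad span {kv['span']!r}")
                if span < 1:
                    raise WigParseError(f"line {lineno}: span must be >= 1")
                if head == "fixedStep":
                    if "start" not in kv:
                        raise WigParseError(f"line {lineno}: fixedStep without start=")
                    try:
                        fixed_pos = int(kv["start"])
                        step = int(kv.get("step", "1"))
                    except ValueError:
                        raise WigParseError(f"line {lineno}: bad start/step")
                    if fixed_pos < 1 or step < 1:
                        raise WigParseError(
                            f"line {lineno}: fixedStep start and step must be >= 1"
                        )
                mode = "variable" if head == "variableStep" else "fixed"
                if cur_chrom not in by_chrom:
                    by_chrom[cur_chrom] = []
                    chrom_order.append(cur_chrom)
                continue
            # data line
            if len(fields) == 4 and mode is None:
                # bedGraph-style: chrom start end value (0-based half-open)
                chrom, s, e, v = fields
                try:
                    s_i, e_i, v_f = int(s), int(e), float(v)
                except ValueError:
                    raise WigParseError(f"line {lineno}: malformed bedGraph line")
                if chrom not in by_chrom:
                    by_chrom[chrom] = []
                    chrom_order.append(chrom)
                by_chrom[chrom].append((s_i, e_i, v_f))
                continue
            if mode == "variable":
                if len(fields) != 2:
                    raise WigParseError(
                        f"line {lineno}: expected 'position value' in variableStep"
                    )
                try:
                    pos, val = int(fields[0]), float(fields[1])
                except ValueError:
                    raise WigParseError(f"line {lineno}: malformed variableStep line")
                if pos < 1:
                    raise WigParseError(f"line {lineno}: WIG positions are 1-based")
                by_chrom[cur_chrom].append((pos - 1, pos - 1 + span, val))
            elif mode == "fixed":
                if len(fields) != 1:
                    raise WigParseError(
                        f"line {lineno}: expected single value in fixedStep"
                    )
                try:
                    val = float(fields[0])
                except ValueError:
                    raise WigParseError(f"line {lineno}: malformed fixedStep value")
                by_chrom[cur_chrom].append((fixed_pos - 1, fixed_pos - 1 + span, val))
                fixed_pos += step
            else:
                raise WigParseError(
                    f"line {lineno}: data line before any step declaration"
                )

    peaks: list[Peak] = []
    for chrom in chrom_order:
        segs = by_chrom[chrom]
        if any(segs[i][0] > segs[i + 1][0] for i in range(len(segs) - 1)):
            logger.warning(
                "%s: positions on %s out of sorted order; reordering", path, chrom
            )
            segs = sorted(segs)
        peaks.extend(_runs_to_peaks(chrom, segs))
    if chrom_order != sorted(chrom_order, key=lambda c: c):
        logger.warning("%s: chromosome blocks out of sorted order; reordering", path)
    return PeakSet(mark=mark, condition=condition, peaks=peaks)


def write_wig(
    peaks: PeakSet, path, name: str | None = None
) -> None:
    """Write a PeakSet as a variableStep WIG of rectangular peaks.

    Each peak is emitted as one span-length value at its max height, so
    AUC is serialized as height x width.  This round-trips exactly for
    rectangular peaks (the synthetic generator and the normalizer only
    produce those); for arbitrary peak shapes the (mean, max, AUC) summary
    cannot be inverted and the AUC is re-derived on read.
    """
    name = name or f"{peaks.mark.value}_{peaks.condition.value}"
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        cur = (None, None)
        for p in peaks:
            width = len(p.interval)
            key = (p.chrom, width)
            if key != cur:
                fh.write(f"variableStep chrom={p.chrom} span={width}\n")
                cur = key
            fh.write(f"{p.interval.start + 1} {p.max_height:.10g}\n")


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED5; score = round(1000 * height / max height)."""
    heights = peaks.heights()
    top = heights.max() if len(heights) else 1.0
    prefix = f"{peaks.mark.value}_{peaks.condition.value}"
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = int(round(1000.0 * p.max_height / top))
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{prefix}_{i}\t{score}\n"
            )


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read the (chrom, start, end) columns of a BED file."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ChipquantError(f"{path}: line {lineno}: fewer than 3 BED columns")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed3(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_annotation(path) -> list[GeneModel]:
    """Read a TSV gene annotation: gene_id, chrom, strand, tss, end3[, cpg_class].

    ``tss`` is the biological 5' position, so tss > end3 on the minus strand.
    Duplicate gene ids are rejected.
    """
    df = pd.read_csv(_open_text(path), sep="\t", dtype=str)
    required = ["gene_id", "chrom", "strand", "tss", "end3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ChipquantError(f"{path}: annotation missing column(s) {missing}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                end3=int(row.end3),
                cpg_class=getattr(row, "cpg_class", "unknown") or "unknown",
            )
        )
    check_same_genome(genes)
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tend3\tcpg_class\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.end3}\t{g.cpg_class}\n"
            )


def read_expression(path, background_level: float) -> ExpressionMatrix:
    """Read a normalized expression TSV (genes x arrays).

    The first column holds gene ids; remaining column headers must encode
    condition and replicate as ``<condition>_<replicate>`` (e.g. ``t0_r1``).
    Missing values and missing conditions are rejected.
    """
    df = pd.read_csv(_open_text(path), sep="\t", index_col=0)
    labels = []
    for col in df.columns:
        if "_" not in col:
            raise ChipquantError(
                f"{path}: array column {col!r} does not encode condition_replicate"
            )
        cond, rep = col.rsplit("_", 1)
        labels.append((Condition.parse(cond), rep))
    values = df.to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values))
    if len(bad):
        g, a = bad[0]
        raise ChipquantError(
            f"{path}: missing value at gene {df.index[g]!r}, array {df.columns[a]!r}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        array_labels=labels,
        values=values,
        background_level=background_level,
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_list(path) -> set[str]:
    """Read a newline-delimited gene-id list (reference gene sets)."""
    with _open_text(path) as fh:
        return {line.strip() for line in fh if line.strip()}
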