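"""Read loading, window assignment, library scaling and densities.

Reads are aligned, deduplicated ChIP-seq tags supplied as BED intervals
(or BAM).  Assignment follows two rules:

* a read contributes to a window iff its alignment interval overlaps the
  window by at least 1 bp (read strand is ignored — ChIP tags are
  unstranded with respect to the template);
* a read whose interval overlaps the annotated spans of more than one
  gene is discarded entirely and tallied (single-gene rule).

Counting is vectorized: for sorted read starts ``S`` and sorted read
ends ``E``, the number of reads overlapping ``[a, b)`` is
``#{S < b} - #{E <= a}``, evaluated with two binary searches.  The
single-gene rule uses the same identity against gene spans to count, per
read, how many gene spans it touches.

Library scaling is linear down-scaling to the smallest library: each
library's counts are multiplied by ``min(totals) / total`` (a factor
<= 1), so effective depths match the library with the fewest mapped
reads.  Scaled counts may be fractional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .gene_models import GenomicInterval, TranscriptModel, WindowSet

__all__ = [
    "ReadRecord",
    "ReadSet",
    "LibraryStats",
    "AssignmentResult",
    "load_reads",
    "assign_reads",
    "library_scale_factors",
    "window_density",
    "binned_profile",
    "profile_matrix",
    "mean_body_depth",
    "reads_to_bed",
    "coverage_bedgraph",
]

logger = logging.getLogger(__name__)


class ReadRecord(NamedTuple):
    """One aligned tag: 0-based half-open span."""

    chrom: str
    start: int
    end: int
    strand: str = "."


@dataclass
class ReadSet:
    """Reads of one library plus its mapped-read total."""

    reads: list[ReadRecord]
    total_mapped_reads: int
    n_skipped: int = 0


@dataclass(frozen=True)
class LibraryStats:
    library_id: str
    condition: str
    mark: str
    total_mapped_reads: int
    scale_factor: float

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValueError(f"{self.library_id}: total_mapped_reads must be > 0")
        if not (0 < self.scale_factor <= 1):
            raise ValueError(f"{self.library_id}: scale_factor must be in (0, 1]")


def load_reads(path) -> ReadSet:
    """Load aligned reads from BED (BED3/BED6) or BAM.

    Invalid intervals (non-integer or end <= start) are skipped and
    counted in ``n_skipped``.  An empty file yields an empty ReadSet;
    the error surfaces at the scaling stage where a zero total is
    rejected.
    """
    path = str(path)
    if path.endswith(".bam"):
        return _load_bam(path)
    reads: list[ReadRecord] = []
    n_skipped = 0
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError):
                n_skipped += 1
                continue
            if end <= start or start < 0:
                n_skipped += 1
                continue
            strand = fields[5] if len(fields) > 5 else "."
            reads.append(ReadRecord(chrom, start, end, strand))
    if n_skipped:
        logger.warning("%s: skipped %d invalid records", path, n_skipped)
    return ReadSet(reads=reads, total_mapped_reads=len(reads), n_skipped=n_skipped)


def _load_bam(path: str) -> ReadSet:
    import pysam

    reads: list[ReadRecord] = []
    n_skipped = 0
    with pysam.AlignmentFile(path, "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_end is None:
                n_skipped += 1
                continue
            reads.append(
                ReadRecord(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                )
            )
    return ReadSet(reads=reads, total_mapped_reads=len(reads), n_skipped=n_skipped)


@dataclass
class AssignmentResult:
    """Per-window raw counts plus the read bookkeeping tallies."""

    counts: pd.DataFrame  # gene_id, transcript_id, window_kind, raw_count, window_length
    total_reads: int
    n_discarded_multi_gene: int
    n_assigned: int
    n_outside: int = field(default=0)


def assign_reads(
    reads: Sequence[ReadRecord],
    window_sets: Mapping[str, WindowSet],
    gene_spans: Mapping[str, GenomicInterval],
    include_flank: bool = False,
) -> AssignmentResult:
    """Assign reads to quantification windows under the single-gene rule.

    ``gene_spans`` are the annotated transcript spans used for the
    multi-gene discard; flank windows deliberately do not participate in
    that rule (upstream flanks routinely reach into neighbours).
    """
    # paired (start, end) read arrays per chromosome
    pairs_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {r.chrom for r in reads}:
        pairs_by_chrom[chrom] = np.asarray(
            [(r.start, r.end) for r in reads if r.chrom == chrom], dtype=np.int64
        )

    # --- single-gene rule: per read, number of gene spans overlapped ---
    span_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in gene_spans.values():
        span_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    kept_pairs: dict[str, np.ndarray] = {}
    n_discarded = 0
    for chrom, pairs in pairs_by_chrom.items():
        spans = span_by_chrom.get(chrom)
        if not spans or len(pairs) == 0:
            kept_pairs[chrom] = pairs
            continue
        sp = np.asarray(spans, dtype=np.int64)
        sp_starts, sp_ends = np.sort(sp[:, 0]), np.sort(sp[:, 1])
        n_spans = np.searchsorted(sp_starts, pairs[:, 1], side="left") - np.searchsorted(
            sp_ends, pairs[:, 0], side="right"
        )
        keep = n_spans <= 1
        n_discarded += int((~keep).sum())
        kept_pairs[chrom] = pairs[keep]

    kept_sorted = {
        chrom: (np.sort(p[:, 0]), np.sort(p[:, 1])) for chrom, p in kept_pairs.items()
    }

    # --- window counts over kept reads ---
    rows = []
    win_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ws in window_sets.values():
        windows: list[tuple[str, GenomicInterval | None]] = [
            ("tss", ws.tss_window),
            ("body", ws.body_window),
        ]
        if include_flank:
            windows.append(("flank", ws.flank_window))
        for kind, iv in windows:
            if iv is None:
                rows.append((ws.gene_id, ws.transcript_id, kind, 0, 0))
                continue
            starts, ends = kept_sorted.get(iv.chrom, (np.empty(0), np.empty(0)))
            count = int(
                np.searchsorted(starts, iv.end, side="left")
                - np.searchsorted(ends, iv.start, side="right")
            )
            rows.append((ws.gene_id, ws.transcript_id, kind, count, len(iv)))
            win_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    # --- conservation tally: kept reads touching at least one window ---
    n_assigned = 0
    for chrom, pairs in kept_pairs.items():
        wins = win_by_chrom.get(chrom)
        if not wins or len(pairs) == 0:
            continue
        wv = np.asarray(wins, dtype=np.int64)
        w_starts, w_ends = np.sort(wv[:, 0]), np.sort(wv[:, 1])
        n_wins = np.searchsorted(w_starts, pairs[:, 1], side="left") - np.searchsorted(
            w_ends, pairs[:, 0], side="right"
        )
        n_assigned += int((n_wins >= 1).sum())

    counts = pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "window_kind", "raw_count", "window_length"]
    )
    total = len(reads)
    return AssignmentResult(
        counts=counts,
        total_reads=total,
        n_discarded_multi_gene=n_discarded,
        n_assigned=n_assigned,
        n_outside=total - n_discarded - n_assigned,
    )


def library_scale_factors(totals: Mapping[str, int]) -> dict[str, float]:
    """Scale factor per library: ``min(totals) / total`` (all <= 1).

    The smallest library gets exactly 1; a zero total is an error.
    """
    if not totals:
        raise ValueError("no libraries supplied")
    for lib, total in totals.items():
        if total <= 0:
            raise ValueError(f"library {lib!r} has non-positive total ({total})")
    smallest = min(totals.values())
    return {lib: smallest / total for lib, total in totals.items()}


def window_density(counts: pd.DataFrame, scale_factor: float = 1.0) -> pd.DataFrame:
    """Attach scaled counts and per-bp densities to a raw count table.

    Density = scaled_count / window_length (reads per bp); windows of
    zero length get NaN density and must stay flagged upstream.
    """
    out = counts.copy()
    out["scaled_count"] = out["raw_count"] * scale_factor
    length = out["window_length"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = out["scaled_count"].to_numpy(dtype=float) / length
    dens[length == 0] = np.nan
    out["density"] = dens
    return out


def _read_midpoints(reads: Iterable[ReadRecord], chrom: str) -> np.ndarray:
    mids = [(r.start + r.end - 1) // 2 for r in reads if r.chrom == chrom]
    return np.asarray(mids, dtype=np.int64)


def binned_profile(
    reads: Sequence[ReadRecord],
    flank_window: GenomicInterval,
    strand: str,
    bin_size: int = 50,
    scale_factor: float = 1.0,
) -> np.ndarray:
    """Binned scaled read counts over a flank window, 5'->3' oriented.

    Reads are binned by their midpoint; minus-strand rows are reversed so
    that bin 0 is always the upstream end in transcript orientation.
    """
    n_bins = len(flank_window) // bin_size
    mids = _read_midpoints(reads, flank_window.chrom)
    offsets = mids - flank_window.start
    inside = (offsets >= 0) & (offsets < n_bins * bin_size)
    row = np.bincount(offsets[inside] // bin_size, minlength=n_bins).astype(float)
    row *= scale_factor
    if strand == "-":
        row = row[::-1]
    return row


def profile_matrix(
    reads: Sequence[ReadRecord],
    window_sets: Mapping[str, WindowSet],
    gene_order: Sequence[str],
    bin_size: int = 50,
    scale_factor: float = 1.0,
) -> pd.DataFrame:
    """Genes x bins matrix of binned scaled counts over flank windows.

    Rows follow ``gene_order`` (typically sorted descending by induced
    gene-body density, mirroring occupancy heat maps); columns are
    transcript-oriented bins with the TSS at offset ``flank_up``.
    """
    rows = {}
    for gene_id in gene_order:
        ws = window_sets[gene_id]
        rows[gene_id] = binned_profile(
            reads, ws.flank_window, ws.strand, bin_size=bin_size, scale_factor=scale_factor
        )
    mat = pd.DataFrame.from_dict(rows, orient="index")
    mat.columns = [f"bin_{i}" for i in range(mat.shape[1])]
    mat.index.name = "gene_id"
    return mat


def mean_body_depth(
    reads: Sequence[ReadRecord],
    body_window: GenomicInterval,
    scale_factor: float = 1.0,
) -> float:
    """Mean per-base scaled coverage depth over a body window.

    Each read contributes to every base it overlaps, so the mean depth
    equals (total overlapped bases inside the window) / window length.
    """
    length = len(body_window)
    total_bases = 0
    for r in reads:
        if r.chrom != body_window.chrom:
            continue
        ov = min(r.end, body_window.end) - max(r.start, body_window.start)
        if ov > 0:
            total_bases += ov
    return scale_factor * total_bases / length


def reads_to_bed(reads: Iterable[ReadRecord]) -> str:
    return "".join(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n" for r in reads)


def coverage_bedgraph(
    reads: Sequence[ReadRecord],
    bin_size: int = 50,
    scale_factor: float = 1.0,
) -> str:
    """4-column bedGraph (0-based half-open) of binned scaled midpoint counts."""
    lines = []
    by_chrom: dict[str, list[int]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append((r.start + r.end - 1) // 2)
    for chrom in sorted(by_chrom):
        mids = np.asarray(by_chrom[chrom], dtype=np.int64)
        bins = mids // bin_size
        counts = np.bincount(bins)
        for b in np.nonzero(counts)[0]:
            lines.append(
                f"{chrom}\t{b * bin_size}\t{(b + 1) * bin_size}\t{counts[b] * scale_factor:g}"
            )
    return "\n".join(lines) + ("\n" if lines else "")
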