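"""Sliding-window enrichment peak calling against a matched input.

A deliberately simple tag-enrichment caller: the genome is tiled in
sliding windows (default 500 bp, step 100 bp); the expected count per
window comes from the depth-matched input library, floored at the
genome-wide mean input per window to guard empty stretches.  A window is
a candidate when

* scaled IP / expected >= ``min_fold`` (default fourfold), and
* the Poisson upper tail of the observed raw IP count at mean
  ``expected / ip_scale`` is significant after Benjamini-Hochberg
  adjustment at the given FDR (default 0.001).

Overlapping or adjacent candidate windows are merged into one peak,
keeping the statistics of the most significant window.  Peak calling is
optional in the pipeline: gene gating can also be satisfied by the
body-density filter alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import ReadRecord, library_scale_factors
from .gene_models import GenomicInterval, TranscriptModel

__all__ = ["PeakCall", "call_peaks", "genes_with_peak", "peaks_to_bed"]


@dataclass(frozen=True)
class PeakCall:
    interval: GenomicInterval
    ip_count: float  # scaled
    expected: float  # scaled
    fold: float
    p_value: float
    q_value: float


def _window_counts(
    reads: Sequence[ReadRecord], chrom: str, win_starts: np.ndarray, window: int
) -> np.ndarray:
    pairs = np.asarray(
        [(r.start, r.end) for r in reads if r.chrom == chrom], dtype=np.int64
    )
    if len(pairs) == 0:
        return np.zeros(len(win_starts), dtype=np.int64)
    starts, ends = np.sort(pairs[:, 0]), np.sort(pairs[:, 1])
    return np.searchsorted(starts, win_starts + window, side="left") - np.searchsorted(
        ends, win_starts, side="right"
    )


def call_peaks(
    ip_reads: Sequence[ReadRecord],
    input_reads: Sequence[ReadRecord],
    window: int = 500,
    step: int = 100,
    min_fold: float = 4.0,
    fdr: float = 0.001,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[PeakCall]:
    """Call enrichment peaks for an IP library over its matched input.

    The IP/input pair is internally depth-matched (both scaled to the
    smaller library).  Raises ValueError when the input library is
    empty: the empirical background cannot be estimated.
    """
    if not ip_reads:
        return []
    if not input_reads:
        raise ValueError("input/background library is empty")
    factors = library_scale_factors(
        {"ip": len(ip_reads), "input": len(input_reads)}
    )
    ip_scale, input_scale = factors["ip"], factors["input"]

    if chrom_sizes is None:
        chrom_sizes = {}
        for r in list(ip_reads) + list(input_reads):
            chrom_sizes[r.chrom] = max(chrom_sizes.get(r.chrom, 0), r.end)

    genome_size = sum(chrom_sizes.values())
    input_mean_per_window = len(input_reads) * input_scale * window / genome_size

    all_chroms: list[str] = []
    all_starts: list[np.ndarray] = []
    all_obs: list[np.ndarray] = []
    all_exp: list[np.ndarray] = []
    for chrom, size in sorted(chrom_sizes.items()):
        win_starts = np.arange(0, max(size - window, 0) + 1, step, dtype=np.int64)
        obs_raw = _window_counts(ip_reads, chrom, win_starts, window)
        inp_raw = _window_counts(input_reads, chrom, win_starts, window)
        expected = np.maximum(inp_raw * input_scale, input_mean_per_window)
        if np.any(expected <= 0):
            raise ValueError("zero expected background; input floor unavailable")
        all_chroms.extend([chrom] * len(win_starts))
        all_starts.append(win_starts)
        all_obs.append(obs_raw)
        all_exp.append(expected)

    win_starts = np.concatenate(all_starts)
    obs_raw = np.concatenate(all_obs)
    expected = np.concatenate(all_exp)
    chroms = np.asarray(all_chroms)

    # Poisson upper tail P(X >= obs) on the raw IP scale
    mu = expected / ip_scale
    p = stats.poisson.sf(obs_raw - 1, mu)
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    fold = obs_raw * ip_scale / expected
    candidate = (fold >= min_fold) & reject & (q <= fdr)

    # merge overlapping/adjacent candidate windows per chromosome
    peaks: list[PeakCall] = []
    idx = np.nonzero(candidate)[0]
    if len(idx) == 0:
        return peaks
    cur: list[int] = [idx[0]]
    for i in idx[1:]:
        same_chrom = chroms[i] == chroms[cur[-1]]
        adjacent = same_chrom and win_starts[i] <= win_starts[cur[-1]] + window
        if adjacent:
            cur.append(i)
        else:
            peaks.append(_merge(cur, chroms, win_starts, window, obs_raw, ip_scale, expected, fold, p, q))
            cur = [i]
    peaks.append(_merge(cur, chroms, win_starts, window, obs_raw, ip_scale, expected, fold, p, q))
    return peaks


def _merge(indices, chroms, win_starts, window, obs_raw, ip_scale, expected, fold, p, q) -> PeakCall:
    best = min(indices, key=lambda i: (p[i], -fold[i]))
    return PeakCall(
        interval=GenomicInterval(
            str(chroms[indices[0]]),
            int(win_starts[indices[0]]),
            int(win_starts[indices[-1]] + window),
        ),
        ip_count=float(obs_raw[best] * ip_scale),
        expected=float(expected[best]),
        fold=float(fold[best]),
        p_value=float(p[best]),
        q_value=float(q[best]),
    )


def genes_with_peak(
    peaks: Sequence[PeakCall],
    genes: Sequence[TranscriptModel],
    slop: int = 2000,
) -> set[str]:
    """Genes whose slopped span [tx_start - slop, tx_end + slop) hits a peak."""
    hit: set[str] = set()
    for t in genes:
        lo, hi = max(t.tx_start - slop, 0), t.tx_end + slop
        for pk in peaks:
            if pk.interval.chrom == t.chrom and pk.interval.start < hi and lo < pk.interval.end:
                hit.add(t.gene_id)
                break
    return hit


def peaks_to_bed(peaks: Sequence[PeakCall]) -> str:
    """BED6+3 export: interval, name, fold as score, '.', ip_count, p, q."""
    lines = []
    for i, pk in enumerate(peaks, start=1):
        iv = pk.interval
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{pk.fold:.3f}\t.\t"
            f"{pk.ip_count:.3f}\t{pk.p_value:.3e}\t{pk.q_value:.3e}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
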