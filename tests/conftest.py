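"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pausekit import pipeline, simdata
from pausekit.coverage import ReadRecord
from pausekit.gene_models import GenomicInterval, TranscriptModel, derive_windows


def overlaps(read: ReadRecord, iv: GenomicInterval | None) -> bool:
    return (
        iv is not None
        and read.chrom == iv.chrom
        and read.start < iv.end
        and iv.start < read.end
    )


def brute_force_assign(reads, window_sets, spans):
    """All-pairs O(n*m) overlap scan: the counting oracle.

    Returns ({(transcript_id, kind): count}, n_discarded) applying the
    multi-gene discard against gene spans, independent of the indexed
    implementation it checks.
    """
    counts = {}
    for ws in window_sets.values():
        for kind, iv in (("tss", ws.tss_window), ("body", ws.body_window)):
            counts[(ws.transcript_id, kind)] = 0
    n_discarded = 0
    for r in reads:
        n_genes = sum(1 for iv in spans.values() if overlaps(r, iv))
        if n_genes > 1:
            n_discarded += 1
            continue
        for ws in window_sets.values():
            for kind, iv in (("tss", ws.tss_window), ("body", ws.body_window)):
                if overlaps(r, iv):
                    counts[(ws.transcript_id, kind)] += 1
    return counts, n_discarded


def pileup_mean_depth(reads, iv: GenomicInterval) -> float:
    """Per-base pileup oracle for mean coverage depth."""
    depth = np.zeros(len(iv), dtype=float)
    for r in reads:
        if r.chrom != iv.chrom:
            continue
        lo, hi = max(r.start, iv.start), min(r.end, iv.end)
        if hi > lo:
            depth[lo - iv.start : hi - iv.start] += 1
    return float(depth.mean())


def poisson_sf_oracle(k: int, mu: float) -> float:
    """Independent Poisson upper tail P(X >= k) by direct summation."""
    if k <= 0:
        return 1.0
    log_term = k * math.log(mu) - mu - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while True:
        total += term
        i += 1
        term *= mu / i
        if term < total * 1e-17 and i > k + 10:
            break
    return total


def random_gene_fixture(rng, n_genes=50, chrom="chrT", genome=200_000):
    """Random (possibly neighbouring) transcripts with derived windows."""
    transcripts = {}
    for i in range(n_genes):
        start = int(rng.integers(2_500, genome - 6_000))
        length = int(rng.integers(600, 5_000))
        strand = "+" if rng.random() < 0.5 else "-"
        t = TranscriptModel(f"g{i}", f"g{i}.t", chrom, strand, start, start + length)
        transcripts[t.gene_id] = t
    spans = {g: t.span for g, t in transcripts.items()}
    windows = {g: derive_windows(t) for g, t in transcripts.items()}
    return transcripts, spans, windows


def random_reads(rng, n_reads=1000, chrom="chrT", genome=200_000, max_len=120):
    reads = []
    for _ in range(n_reads):
        start = int(rng.integers(0, genome))
        length = int(rng.integers(20, max_len))
        reads.append(ReadRecord(chrom, start, start + length))
    return reads


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """A moderate three-condition synthetic dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("simdata")
    return simdata.simulate_contrast(
        outdir,
        n_genes=60,
        frac_activated=0.5,
        release_factor=3.0,
        conditions=("S0", "S15", "S15+inhibitor"),
        marks=("PolII", "gH2AX", "input"),
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_run(sim_dataset):
    """The S0-vs-S15 contrast run on the shared dataset."""
    config = pipeline.ContrastConfig(
        sheet_path=str(sim_dataset.sheet_path),
        annotation_path=str(sim_dataset.gtf_path),
        condition_a="S0",
        condition_b="S15",
        marks=("PolII", "gH2AX"),
        n_boot=2_000,
        seed=5,
    )
    return pipeline.run_contrast(config)
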