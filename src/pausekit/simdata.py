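"""Synthetic ChIP-seq datasets with known generative truth.

The generator emulates the structure of a serum-induction Pol II
pausing study on a synthetic chromosome: per gene, a sharp TSS-proximal
read peak (paused Pol II, truncated-normal read anchors within the
TSS-proximal window), a diffuse uniform gene-body component, and uniform
genome background.  Conditions modulate the gene body:

* ``S0`` (uninduced baseline): body rate ``lambda_body``;
* ``S15`` (serum induced): body rate multiplied by the gene's
  ``release_factor`` (pause release — Pol II moves into the body);
* ``S15+inhibitor`` (e.g., DNA-PKcs inhibition): release blocked — body
  rate stays at baseline while the TSS component is multiplied by a
  retention factor >= 1 (default 1.3), emulating Pol II accumulating at
  the TSS when release is prevented.

Elongation-coupled DDR marks (γH2AX-like, S2 Pol II-like) carry only the
body-proportional component and are confined, by construction, to
transcript-oriented offsets ``[-150, tx_length)`` — the signal tracks
elongating Pol II and never spreads outside the transcribed unit.
The input mark is uniform background only.

Every per-gene expectation (densities, pausing index) is available in
closed form, making the generator the oracle for parameter-recovery
tests.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import ReadRecord, reads_to_bed
from .gene_models import (
    BODY_OFFSET,
    TSS_HALFWIDTH,
    TranscriptModel,
    transcripts_to_gtf,
)

__all__ = [
    "SimGeneSpec",
    "SimDataset",
    "make_panel",
    "simulate_library",
    "expected_pausing_index",
    "expected_densities",
    "simulate_contrast",
    "truth_table",
]

CONDITIONS = ("S0", "S15", "S15+inhibitor")
IP_MARKS = ("PolII", "S2PolII", "gH2AX")
#: fraction of the input background rate also present in IP libraries
IP_BACKGROUND_FRACTION = 0.1
#: default TSS retention factor under blocked release
TSS_RETENTION = 1.3
DEFAULT_READ_LENGTH = 36


@dataclass(frozen=True)
class SimGeneSpec:
    """Generative parameters of one synthetic gene.

    ``lambda_tss`` is the expected read count in the TSS peak (per unit
    depth), ``lambda_body`` the expected reads per bp in the gene body,
    ``release_factor`` the multiplicative body-rate change on induction
    (1 = not released).  The paused-peak centre sits ``peak_offset`` bp
    downstream of the TSS with spread ``peak_sd``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tx_length: int
    lambda_tss: float
    lambda_body: float
    release_factor: float = 1.0
    peak_offset: int = 50
    peak_sd: float = 30.0

    def __post_init__(self) -> None:
        if self.tx_length <= 550:
            raise ValueError("tx_length must exceed 550 so a usable body exists")
        if min(self.lambda_tss, self.lambda_body) < 0 or self.release_factor < 0:
            raise ValueError("rates must be non-negative")

    def to_transcript(self) -> TranscriptModel:
        if self.strand == "+":
            tx_start, tx_end = self.tss, self.tss + self.tx_length
        else:
            tx_start, tx_end = self.tss + 1 - self.tx_length, self.tss + 1
        return TranscriptModel(
            gene_id=self.gene_id,
            transcript_id=f"{self.gene_id}.t1",
            chrom=self.chrom,
            strand=self.strand,
            tx_start=tx_start,
            tx_end=tx_end,
        )


def _condition_rates(spec: SimGeneSpec, condition: str, tss_retention: float):
    """(TSS multiplier, body multiplier) for a condition."""
    if condition == "S0":
        return 1.0, 1.0
    if condition == "S15":
        return 1.0, spec.release_factor
    if condition == "S15+inhibitor":
        return tss_retention, 1.0
    raise ValueError(f"unknown condition: {condition!r}")


def expected_densities(
    spec: SimGeneSpec,
    condition: str,
    tss_retention: float = TSS_RETENTION,
) -> tuple[float, float]:
    """Closed-form expected (tss_density, body_density) at unit depth.

    TSS density spreads the peak's expected count over the 300-bp
    TSS-proximal window; body density is the per-bp body rate times the
    condition's release multiplier.  Background is excluded (signal-only
    expectation).
    """
    t_mult, b_mult = _condition_rates(spec, condition, tss_retention)
    return (
        spec.lambda_tss * t_mult / (2 * TSS_HALFWIDTH),
        spec.lambda_body * b_mult,
    )


def expected_pausing_index(
    spec: SimGeneSpec,
    condition: str,
    tss_retention: float = TSS_RETENTION,
) -> float:
    """Plug-in expected PI: expected TSS density over expected body density."""
    tss_d, body_d = expected_densities(spec, condition, tss_retention)
    if body_d <= 0:
        raise ValueError("expected PI undefined at zero body rate")
    return tss_d / body_d


def make_panel(
    n_genes: int = 200,
    frac_activated: float = 0.5,
    release_factor: float = 3.0,
    seed: int = 0,
    chrom: str = "simchr1",
    gap: int = 10_000,
    tx_length_range: tuple[int, int] = (2_000, 6_000),
    lambda_body_range: tuple[float, float] = (0.2, 0.5),
    pi_range: tuple[float, float] = (2.0, 8.0),
) -> list[SimGeneSpec]:
    """Lay out a gene panel on one synthetic chromosome with >= `gap` spacing.

    A ``frac_activated`` fraction of genes (chosen at random) receives
    the given release factor; the rest keep factor 1.  TSS rates are set
    so the baseline expected PI is uniform in ``pi_range`` given the
    body rate: ``lambda_tss = PI * 300 * lambda_body``.
    """
    rng = np.random.default_rng(seed)
    n_act = round(n_genes * frac_activated)
    activated = np.zeros(n_genes, dtype=bool)
    activated[rng.choice(n_genes, size=n_act, replace=False)] = True
    specs = []
    cursor = gap
    for i in range(n_genes):
        tx_length = int(rng.integers(*tx_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        lam_body = float(rng.uniform(*lambda_body_range))
        pi = float(rng.uniform(*pi_range))
        tss = cursor if strand == "+" else cursor + tx_length - 1
        specs.append(
            SimGeneSpec(
                gene_id=f"SIMG{i:04d}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                tx_length=tx_length,
                lambda_tss=pi * 2 * TSS_HALFWIDTH * lam_body,
                lambda_body=lam_body,
                release_factor=release_factor if activated[i] else 1.0,
            )
        )
        cursor += tx_length + gap
    return specs


def _check_non_overlapping(specs) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in specs:
        t = s.to_transcript()
        by_chrom.setdefault(s.chrom, []).append((t.tx_start, t.tx_end))
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping gene specs on {chrom}")


def _place_reads(anchors: np.ndarray, strand: str, read_length: int, chrom: str) -> list[ReadRecord]:
    """Genomic anchor -> read interval, oriented with transcription."""
    reads = []
    for g in anchors:
        g = int(g)
        if strand == "-":
            reads.append(ReadRecord(chrom, g - read_length + 1, g + 1, "-"))
        else:
            reads.append(ReadRecord(chrom, g, g + read_length, "+"))
    return reads


def simulate_library(
    specs: list[SimGeneSpec],
    condition: str,
    mark: str,
    background_rate: float = 0.1,
    read_length: int = DEFAULT_READ_LENGTH,
    depth_factor: float = 1.0,
    seed: int = 0,
    tss_retention: float = TSS_RETENTION,
    chrom_length: int | None = None,
) -> list[ReadRecord]:
    """Simulate one {condition x mark} library.

    Pol II: per gene, Poisson(lambda_tss * depth * tss_mult) anchors from
    a truncated normal within the TSS-proximal window plus
    Poisson(lambda_body * body_length * depth * body_mult) anchors
    uniform over the body.  DDR/elongation marks: the body-proportional
    component only, uniform over transcript offsets [-150, tx_length)
    and clamped so read intervals stay inside those gene boundaries.
    Input: uniform genome background at ``background_rate`` reads/bp
    (the default 0.1 gives the input library a depth comparable to the
    IP libraries, as in a matched sequencing design); IP marks receive
    a small fraction of that background as well.
    """
    _check_non_overlapping(specs)
    if mark not in IP_MARKS and mark != "input":
        raise ValueError(f"unknown mark: {mark!r}")
    rng = np.random.default_rng(seed)
    chroms = sorted({s.chrom for s in specs})
    if chrom_length is None:
        chrom_length = max(
            max(s.to_transcript().tx_end for s in specs) + 10_000, 1
        )
    reads: list[ReadRecord] = []

    if mark != "input":
        for spec in specs:
            t_mult, b_mult = _condition_rates(spec, condition, tss_retention)
            strand, chrom, tss = spec.strand, spec.chrom, spec.tss

            if mark == "PolII":
                # paused peak: truncated-normal anchors in [-150, +150)
                n_tss = rng.poisson(spec.lambda_tss * depth_factor * t_mult)
                if n_tss:
                    lo, hi = -TSS_HALFWIDTH, TSS_HALFWIDTH - 1
                    a = (lo - spec.peak_offset) / spec.peak_sd
                    b = (hi - spec.peak_offset) / spec.peak_sd
                    offsets = stats.truncnorm.rvs(
                        a, b, loc=spec.peak_offset, scale=spec.peak_sd,
                        size=n_tss, random_state=rng,
                    )
                    offsets = np.clip(np.rint(offsets), lo, hi).astype(np.int64)
                    anchors = tss + offsets if strand == "+" else tss - offsets
                    reads.extend(_place_reads(anchors, strand, read_length, chrom))
                # gene body: uniform anchors in [+250, tx_length - read_length)
                body_len = spec.tx_length - BODY_OFFSET
                n_body = rng.poisson(spec.lambda_body * body_len * depth_factor * b_mult)
                if n_body:
                    offsets = rng.integers(
                        BODY_OFFSET, spec.tx_length - read_length, size=n_body
                    )
                    anchors = tss + offsets if strand == "+" else tss - offsets
                    reads.extend(_place_reads(anchors, strand, read_length, chrom))
            else:
                # elongation-coupled mark: body-proportional, confined to
                # transcript offsets [-150, tx_length)
                body_len = spec.tx_length - BODY_OFFSET
                n = rng.poisson(spec.lambda_body * body_len * depth_factor * b_mult)
                if n:
                    offsets = rng.integers(
                        -TSS_HALFWIDTH, spec.tx_length - read_length, size=n
                    )
                    anchors = tss + offsets if strand == "+" else tss - offsets
                    reads.extend(_place_reads(anchors, strand, read_length, chrom))

    bg_rate = background_rate if mark == "input" else background_rate * IP_BACKGROUND_FRACTION
    if bg_rate > 0:
        for chrom in chroms:
            n_bg = rng.poisson(bg_rate * chrom_length * depth_factor)
            if n_bg:
                starts = rng.integers(0, max(chrom_length - read_length, 1), size=n_bg)
                reads.extend(
                    ReadRecord(chrom, int(s), int(s) + read_length, "+") for s in starts
                )
    return reads


def truth_table(
    specs: list[SimGeneSpec],
    conditions=("S0", "S15"),
    tss_retention: float = TSS_RETENTION,
) -> pd.DataFrame:
    """Per-gene, per-condition closed-form expectations and flags."""
    rows = []
    for spec in specs:
        for cond in conditions:
            tss_d, body_d = expected_densities(spec, cond, tss_retention)
            rows.append(
                {
                    "gene_id": spec.gene_id,
                    "condition": cond,
                    "expected_tss_density": tss_d,
                    "expected_body_density": body_d,
                    "expected_pi": tss_d / body_d if body_d > 0 else np.nan,
                    "release_factor": spec.release_factor,
                    "activated": spec.release_factor > 1.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SimDataset:
    """Paths and truth of one written synthetic contrast dataset."""

    outdir: Path
    gtf_path: Path
    sheet_path: Path
    truth_path: Path
    specs: list[SimGeneSpec] = field(repr=False)
    truth: pd.DataFrame = field(repr=False)
    library_paths: dict[tuple[str, str], Path] = field(default_factory=dict)


def simulate_contrast(
    outdir,
    n_genes: int = 200,
    frac_activated: float = 0.5,
    release_factor: float = 3.0,
    conditions=("S0", "S15"),
    marks=("PolII", "gH2AX", "input"),
    background_rate: float = 0.1,
    depth_factors: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    tss_retention: float = TSS_RETENTION,
    **panel_kwargs,
) -> SimDataset:
    """Write a self-consistent synthetic dataset to ``outdir``.

    Emits: ``annotation.gtf``, one BED per {condition x mark}
    (``reads_<condition>_<mark>.bed``), a library sheet
    (``libraries.tsv``: library_id, condition, mark, path) and the truth
    table (``truth.tsv``).  Library depth factors default to a modest
    deterministic disparity across libraries so that scaling is
    exercised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    panel_seed, *lib_seeds = [int(s) for s in ss.generate_state(1 + len(conditions) * len(marks))]
    specs = make_panel(
        n_genes=n_genes,
        frac_activated=frac_activated,
        release_factor=release_factor,
        seed=panel_seed % (2**31),
        **panel_kwargs,
    )
    transcripts = [s.to_transcript() for s in specs]
    gtf_path = outdir / "annotation.gtf"
    gtf_path.write_text(transcripts_to_gtf(transcripts))

    default_depths = [1.0, 0.7, 0.85, 0.6, 0.9, 0.75, 0.8, 0.65, 0.95]
    sheet_rows = []
    library_paths = {}
    i = 0
    for cond in conditions:
        for mark in marks:
            depth = (
                depth_factors.get((cond, mark), 1.0)
                if depth_factors is not None
                else default_depths[i % len(default_depths)]
            )
            lib_seed = lib_seeds[i] % (2**31)
            reads = simulate_library(
                specs,
                cond,
                mark,
                background_rate=background_rate,
                depth_factor=depth,
                seed=lib_seed,
                tss_retention=tss_retention,
            )
            safe_cond = cond.replace("+", "_")
            path = outdir / f"reads_{safe_cond}_{mark}.bed"
            path.write_text(reads_to_bed(reads))
            lib_id = f"{safe_cond}_{mark}"
            sheet_rows.append(
                {"library_id": lib_id, "condition": cond, "mark": mark, "path": str(path)}
            )
            library_paths[(cond, mark)] = path
            i += 1

    sheet = pd.DataFrame(sheet_rows)
    sheet_path = outdir / "libraries.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    truth = truth_table(specs, conditions=conditions, tss_retention=tss_retention)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimDataset(
        outdir=outdir,
        gtf_path=gtf_path,
        sheet_path=sheet_path,
        truth_path=truth_path,
        specs=specs,
        truth=truth,
        library_paths=library_paths,
    )
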