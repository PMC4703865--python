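"""Gene annotation models and strand-aware quantification windows.

This module parses Ensembl-dialect GTF annotation into lightweight
transcript models, selects one primary transcript per gene (maximum
gene-body read density), and derives the three windows used throughout
the analysis:

* **TSS-proximal window** — ``[TSS-150, TSS+150)`` in transcript
  orientation (300 bp, TSS at offset 150);
* **gene-body window** — from +250 downstream of the TSS to the
  transcript 3' end;
* **flank window** — ``[-2000, +2500)`` about the TSS, used for
  TSS-centred profile matrices.

All internal coordinates are 0-based half-open.  GTF input (1-based
inclusive) and BED input (0-based half-open) are converted at the
boundary.  On the minus strand a transcript-coordinate offset ``o`` maps
to genomic position ``tss - o``, so a transcript window ``[o1, o2)``
becomes the genomic interval ``[tss - o2 + 1, tss - o1 + 1)``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

from gffutils.feature import feature_from_line

__all__ = [
    "AnnotationError",
    "GenomicInterval",
    "TranscriptModel",
    "WindowSet",
    "parse_annotation",
    "select_primary_transcript",
    "derive_windows",
    "gene_spans",
    "transcripts_to_gtf",
    "windows_to_bed",
]

#: default TSS-proximal half width (bp)
TSS_HALFWIDTH = 150
#: default gene-body offset downstream of the TSS (bp)
BODY_OFFSET = 250
#: default flank extents about the TSS (bp)
FLANK_UP = 2000
FLANK_DOWN = 2500
#: bodies shorter than this are flagged and excluded from pausing statistics
MIN_BODY_LENGTH = 200


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated transcript with its 5' end (TSS) resolved by strand."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise ValueError(
                f"{self.transcript_id}: tx_end ({self.tx_end}) <= tx_start ({self.tx_start})"
            )

    @property
    def tss(self) -> int:
        """Genomic position of the 5' end: tx_start on '+', tx_end-1 on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tx_length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)


@dataclass(frozen=True)
class WindowSet:
    """Quantification windows for one transcript.

    ``body_window`` is ``None`` when the transcript is too short to host
    a body window at all; ``body_valid`` is False whenever the body is
    absent or shorter than the minimum usable length, in which case the
    gene is excluded from pausing statistics (but not from profiles).
    """

    gene_id: str
    transcript_id: str
    strand: str
    tss_window: GenomicInterval
    body_window: GenomicInterval | None
    flank_window: GenomicInterval
    body_length: int
    body_valid: bool


def _transcript_window(
    tss: int, strand: str, chrom: str, o1: int, o2: int
) -> GenomicInterval | None:
    """Map transcript-coordinate window [o1, o2) to a genomic interval.

    Clipped at chromosome position 0; returns None if clipping empties it.
    """
    if strand == "+":
        start, end = tss + o1, tss + o2
    else:
        start, end = tss - o2 + 1, tss - o1 + 1
    start = max(start, 0)
    if end <= start:
        return None
    return GenomicInterval(chrom, start, end)


def derive_windows(
    t: TranscriptModel,
    tss_halfwidth: int = TSS_HALFWIDTH,
    body_offset: int = BODY_OFFSET,
    flank_up: int = FLANK_UP,
    flank_down: int = FLANK_DOWN,
    min_body_length: int = MIN_BODY_LENGTH,
) -> WindowSet:
    """Derive TSS-proximal, gene-body and flank windows for a transcript.

    Windows are strand-aware (transcript offset +x lies downstream in the
    direction of transcription) and clipped at chromosome start.  Short
    transcripts yield a flagged (invalid) body window rather than an error.
    """
    tss = t.tss
    tss_win = _transcript_window(tss, t.strand, t.chrom, -tss_halfwidth, tss_halfwidth)
    if tss_win is None:  # pragma: no cover - needs a TSS within 150 bp of pos 0
        raise AnnotationError(f"{t.transcript_id}: TSS window fully clipped")
    flank = _transcript_window(tss, t.strand, t.chrom, -flank_up, flank_down)
    assert flank is not None
    body_len = t.tx_length - body_offset
    body = None
    if body_len > 0:
        body = _transcript_window(tss, t.strand, t.chrom, body_offset, t.tx_length)
    body_valid = body is not None and body_len >= min_body_length
    return WindowSet(
        gene_id=t.gene_id,
        transcript_id=t.transcript_id,
        strand=t.strand,
        tss_window=tss_win,
        body_window=body,
        flank_window=flank,
        body_length=max(body_len, 0),
        body_valid=body_valid,
    )


def _iter_lines(source) -> Iterator[tuple[int, str]]:
    if isinstance(source, (str, bytes)):
        handle: TextIO = open(source)
        close = True
    elif hasattr(source, "read"):
        handle, close = source, False
    else:  # iterable of lines
        handle, close = iter(source), False
    try:
        for i, line in enumerate(handle, start=1):
            yield i, line
    finally:
        if close:
            handle.close()


def parse_annotation(
    gtf_source,
    feature_types: Sequence[str] = ("transcript",),
    protein_coding_only: bool = True,
) -> dict[str, list[TranscriptModel]]:
    """Parse GTF annotation into transcript models grouped by gene.

    Parameters
    ----------
    gtf_source
        Path, open text handle, or iterable of GTF lines (Ensembl
        dialect: attributes carry ``gene_id`` and ``transcript_id``).
    feature_types
        Feature types to retain (transcript records carry the full span).
    protein_coding_only
        When True, drop transcripts whose ``gene_biotype`` (or
        ``transcript_biotype``) attribute is present and not
        ``protein_coding``.  Records without the attribute are kept.

    Returns
    -------
    dict mapping gene_id to its transcripts, coordinates converted to the
    internal 0-based half-open convention.

    Raises
    ------
    AnnotationError
        For a malformed line, naming the offending line number.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for lineno, line in _iter_lines(gtf_source):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            feat = feature_from_line(line, strict=False)
            featuretype = feat.featuretype
            start_1based, end = int(feat.start), int(feat.end)
        except Exception as exc:
            raise AnnotationError(f"malformed GTF line {lineno}: {exc}") from exc
        if featuretype not in feature_types:
            continue
        attrs = feat.attributes
        if "gene_id" not in attrs or "transcript_id" not in attrs:
            raise AnnotationError(
                f"malformed GTF line {lineno}: missing gene_id/transcript_id"
            )
        if protein_coding_only:
            biotype = (attrs.get("gene_biotype") or attrs.get("transcript_biotype") or [None])[0]
            if biotype is not None and biotype != "protein_coding":
                continue
        tx_start, tx_end = start_1based - 1, end
        if tx_end <= tx_start:
            warnings.warn(
                f"GTF line {lineno}: transcript with end <= start rejected",
                stacklevel=2,
            )
            continue
        model = TranscriptModel(
            gene_id=attrs["gene_id"][0],
            transcript_id=attrs["transcript_id"][0],
            chrom=feat.seqid,
            strand=feat.strand,
            tx_start=tx_start,
            tx_end=tx_end,
        )
        by_gene.setdefault(model.gene_id, []).append(model)
    return by_gene


def select_primary_transcript(
    transcripts: Sequence[TranscriptModel],
    body_density_by_transcript: Mapping[str, float],
) -> str:
    """Select the primary transcript of one gene: maximum body-read density.

    Ties are broken by greater transcript length, then lexicographically
    smaller transcript_id, so the choice is deterministic.
    """
    if not transcripts:
        raise ValueError("no transcripts supplied")
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in body_density_by_transcript]
    if missing:
        raise KeyError(f"no body density for transcripts: {missing}")
    best = min(
        transcripts,
        key=lambda t: (
            -body_density_by_transcript[t.transcript_id],
            -t.tx_length,
            t.transcript_id,
        ),
    )
    return best.transcript_id


def gene_spans(
    transcripts_by_gene: Mapping[str, Sequence[TranscriptModel]],
) -> dict[str, GenomicInterval]:
    """Union annotated span per gene (min start to max end over transcripts).

    Used by the single-gene read rule: a read overlapping more than one
    gene's span is discarded from quantification.
    """
    spans: dict[str, GenomicInterval] = {}
    for gene_id, models in transcripts_by_gene.items():
        chroms = {t.chrom for t in models}
        if len(chroms) != 1:
            raise AnnotationError(f"gene {gene_id} spans multiple chromosomes")
        spans[gene_id] = GenomicInterval(
            chroms.pop(),
            min(t.tx_start for t in models),
            max(t.tx_end for t in models),
        )
    return spans


def transcripts_to_gtf(
    transcripts: Iterable[TranscriptModel],
    source: str = "pausekit",
    gene_biotype: str = "protein_coding",
) -> str:
    """Serialize transcript models back to Ensembl-dialect GTF text."""
    out = io.StringIO()
    for t in transcripts:
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_biotype "{gene_biotype}";'
        )
        out.write(
            f"{t.chrom}\t{source}\ttranscript\t{t.tx_start + 1}\t{t.tx_end}\t.\t"
            f"{t.strand}\t.\t{attrs}\n"
        )
    return out.getvalue()


def windows_to_bed(window_sets: Iterable[WindowSet]) -> str:
    """Export windows as 6-column BED (name = gene|transcript|kind)."""
    lines = []
    for ws in window_sets:
        for kind, iv in (
            ("tss", ws.tss_window),
            ("body", ws.body_window),
            ("flank", ws.flank_window),
        ):
            if iv is None:
                continue
            name = f"{ws.gene_id}|{ws.transcript_id}|{kind}"
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{ws.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
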