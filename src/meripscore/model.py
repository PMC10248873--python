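"""Annotation and peak data model with exact interval arithmetic.

All coordinates are internally 0-based half-open ``[start, end)`` on a named
chromosome; GTF's 1-based closed convention is converted at the file
boundary (see :mod:`meripscore.io`).  Peaks are treated as strandless —
MeRIP peak calling is performed on unstranded fragment coverage, so strand
information is taken from the gene side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Transcript",
    "Gene",
    "Peak",
    "CoverageTrack",
    "overlap_length",
    "merge_intervals",
    "intersect_length",
    "compute_peak_signal",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 across chromosomes.

    Strand is ignored.  Half-open semantics: adjacent intervals
    (``a.end == b.start``) overlap by 0.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Merge possibly-overlapping intervals into a sorted disjoint union.

    All intervals must share one chromosome; the merged intervals carry
    strand "." because a union over transcripts has no single strand.
    """
    ivs = sorted(intervals, key=lambda i: (i.start, i.end))
    if not ivs:
        return ()
    chroms = {i.chrom for i in ivs}
    if len(chroms) > 1:
        raise ValueError(f"cannot merge intervals across chromosomes: {sorted(chroms)}")
    chrom = ivs[0].chrom
    merged: list[list[int]] = [[ivs[0].start, ivs[0].end]]
    for iv in ivs[1:]:
        if iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return tuple(GenomicInterval(chrom, s, e) for s, e in merged)


def intersect_length(query: GenomicInterval, targets: Sequence[GenomicInterval]) -> int:
    """Total bp of ``query`` covered by a disjoint interval set."""
    return sum(overlap_length(query, t) for t in targets)


@dataclass(frozen=True)
class Transcript:
    """One isoform: an ordered exon chain, optionally with a CDS.

    ``exons`` are non-overlapping and sorted by start on one chromosome and
    strand.  ``cds`` holds the genomic CDS intervals (subset of exonic
    space) when the annotation provides them; UTR segmentation is derived
    from it.  ``length`` is the spliced (mature-transcript) length — the
    quantity meant by "transcript length" in an RNA context.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(self.cds, key=lambda e: e.start)))
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons on multiple chromosomes/strands"
            )
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    def spliced_position(self, pos: int) -> Optional[int]:
        """Map a genomic base to its 5'→3' spliced coordinate, or None.

        Returns None when ``pos`` is intronic or outside the transcript.
        On the minus strand the spliced coordinate counts from the
        3'-most genomic base.
        """
        offset = 0
        hit = None
        for exon in self.exons:
            if exon.start <= pos < exon.end:
                hit = offset + (pos - exon.start)
                break
            offset += exon.length
        if hit is None:
            return None
        if self.strand == "-":
            return self.length - 1 - hit
        return hit

    # --- CDS / UTR segmentation (spliced lengths) -------------------------
    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)

    def utr_lengths(self) -> Optional[tuple[int, int]]:
        """Spliced (5'UTR, 3'UTR) lengths, or None without CDS annotation."""
        if not self.cds:
            return None
        cds_min, cds_max = self.cds[0].start, self.cds[-1].end
        left = sum(min(e.end, cds_min) - e.start for e in self.exons if e.start < cds_min)
        right = sum(e.end - max(e.start, cds_max) for e in self.exons if e.end > cds_max)
        if self.strand == "-":
            left, right = right, left
        return left, right

    def utr_intervals(self) -> Optional[tuple[tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]]]:
        """Genomic (5'UTR, 3'UTR) interval lists, or None without CDS."""
        if not self.cds:
            return None
        cds_min, cds_max = self.cds[0].start, self.cds[-1].end
        left: list[GenomicInterval] = []
        right: list[GenomicInterval] = []
        for e in self.exons:
            if e.start < cds_min:
                left.append(GenomicInterval(e.chrom, e.start, min(e.end, cds_min), e.strand))
            if e.end > cds_max and max(e.start, cds_max) < e.end:
                right.append(GenomicInterval(e.chrom, max(e.start, cds_max), e.end, e.strand))
        if self.strand == "-":
            left, right = right, left
        return tuple(left), tuple(right)


@dataclass(frozen=True)
class Gene:
    """A gene: one or more transcripts sharing chromosome and strand."""

    gene_id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        object.__setattr__(
            self,
            "transcripts",
            tuple(sorted(self.transcripts, key=lambda t: t.transcript_id)),
        )
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        ids = {t.gene_id for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {self.gene_id}: transcripts on multiple chromosomes/strands")
        if ids != {self.gene_id}:
            raise ValueError(f"gene {self.gene_id}: transcript gene_id mismatch {ids}")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exon_union(self) -> tuple[GenomicInterval, ...]:
        return merge_intervals(e for t in self.transcripts for e in t.exons)

    @property
    def longest_transcript(self) -> Transcript:
        """Longest isoform by spliced length; ties broken by smallest id."""
        return min(self.transcripts, key=lambda t: (-t.length, t.transcript_id))

    @property
    def tss(self) -> int:
        """Transcription start position of the gene span (strand-aware)."""
        return self.span.end - 1 if self.strand == "-" else self.span.start


@dataclass(frozen=True)
class Peak:
    """One called m6A peak.

    ``signal`` is the peak methylation level m_p — by default the peak
    caller's enrichment (narrowPeak signalValue), optionally recomputed
    from coverage tracks via :func:`compute_peak_signal`.  ``summit_offset``
    follows narrowPeak column 10 (-1 = unknown; categorisation then falls
    back to the peak midpoint).
    """

    interval: GenomicInterval
    signal: float
    group: str = ""
    replicate: str = ""
    summit_offset: int = -1
    q_value: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak {self.name or self.interval}: negative signal {self.signal}")
        if self.summit_offset >= self.interval.length:
            raise ValueError(
                f"peak {self.name or self.interval}: summit_offset {self.summit_offset} "
                f">= length {self.interval.length}"
            )

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def summit(self) -> int:
        """Genomic summit position (midpoint when the summit is unknown)."""
        if self.summit_offset >= 0:
            return self.interval.start + self.summit_offset
        return self.interval.start + self.interval.length // 2


class CoverageTrack:
    """Stepwise read-depth track (bedGraph semantics).

    Uncovered positions inside a chromosome's extent have depth 0; a query
    outside the recorded extent is an error, since silence there is
    indistinguishable from missing data.
    """

    def __init__(self, segments: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.extent: dict[str, tuple[int, int]] = {}
        for chrom, segs in segments.items():
            segs = sorted(segs)
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            vals = np.array([v for _, _, v in segs], dtype=float)
            if np.any(ends <= starts):
                raise ValueError(f"coverage track {chrom}: empty or inverted segment")
            self._chroms[chrom] = (starts, ends, vals)
            self.extent[chrom] = (int(starts[0]), int(ends[-1]))

    def mean_depth(self, interval: GenomicInterval) -> float:
        if interval.chrom not in self._chroms:
            raise ValueError(f"coverage track has no chromosome {interval.chrom!r}")
        lo, hi = self.extent[interval.chrom]
        if interval.start < lo or interval.end > hi:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} outside "
                f"track extent [{lo}, {hi})"
            )
        starts, ends, vals = self._chroms[interval.chrom]
        ov = np.maximum(
            0, np.minimum(ends, interval.end) - np.maximum(starts, interval.start)
        )
        return float(np.dot(ov, vals) / interval.length)


def compute_peak_signal(
    peak: Peak,
    ip_coverage: CoverageTrack,
    input_coverage: CoverageTrack,
    mode: str = "difference",
    pseudocount: float = 1.0,
) -> float:
    """Peak methylation level from IP vs input coverage.

    ``difference`` returns ``max(0, mean_IP - mean_input)`` over the peak
    (the IGV-style IP-minus-input abundance); ``ratio`` returns
    ``(mean_IP + eps) / (mean_input + eps)`` with a pseudo-count eps
    (default 1) guarding against zero input depth.
    """
    if mode not in ("difference", "ratio"):
        raise ValueError(f"unknown signal mode {mode!r}")
    try:
        ip = ip_coverage.mean_depth(peak.interval)
        inp = input_coverage.mean_depth(peak.interval)
    except ValueError as exc:
        raise ValueError(f"peak {peak.name or peak.interval}: {exc}") from exc
    if mode == "difference":
        return max(0.0, ip - inp)
    return (ip + pseudocount) / (inp + pseudocount)
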