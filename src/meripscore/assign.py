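"""Peak-to-gene assignment, feature categorisation and metagene positions.

The admission rule assigns a peak to every gene whose span contains at
least ``min_fraction`` (default 50%) of the peak's length.  A peak may be
assigned to several overlapping genes, or to none; each receiving gene
counts the peak in its score.

Feature categories are decided by the peak summit (midpoint fallback)
tested against the classes in a configurable precedence order, so every
peak receives exactly one label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import Gene, GenomicInterval, Peak, Transcript, intersect_length, overlap_length

logger = logging.getLogger(__name__)

__all__ = [
    "PeakAssignment",
    "FEATURE_LABELS",
    "DEFAULT_PRECEDENCE",
    "AnnotationIndex",
    "assign_peaks",
    "categorize_peak",
    "region_proportions",
    "metagene_position",
    "metagene_table",
]

FEATURE_LABELS = ("promoter", "5UTR", "CDS", "3UTR", "other_exon", "intron", "intergenic")

# UTR/CDS before generic exon, genic classes before promoter.
DEFAULT_PRECEDENCE = ("5UTR", "3UTR", "CDS", "other_exon", "promoter", "intron", "intergenic")


@dataclass(frozen=True)
class PeakAssignment:
    """One (peak, gene) admission under the overlap-fraction rule."""

    peak: Peak
    gene_id: str
    overlap_fraction: float
    exon_overlap: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError(f"overlap_fraction {self.overlap_fraction} outside [0, 1]")
        if self.exon_overlap > self.peak.length:
            raise ValueError("exon_overlap exceeds peak length")


class AnnotationIndex:
    """Interval-tree index over gene spans and feature regions.

    Built once per annotation and shared by assignment, categorisation and
    proportion computations.
    """

    def __init__(self, genes: Iterable[Gene], promoter_window: int = 2000):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        self.promoter_window = promoter_window
        self._span_trees: dict[str, IntervalTree] = {}
        self._promoter_trees: dict[str, IntervalTree] = {}
        self._features: dict[str, dict[str, tuple[GenomicInterval, ...]]] = {}
        for g in self.genes.values():
            span = g.span
            self._span_trees.setdefault(g.chrom, IntervalTree()).addi(span.start, span.end, g.gene_id)
            if g.strand == "-":
                ps, pe = span.end, span.end + promoter_window
            else:
                ps, pe = max(0, span.start - promoter_window), span.start
            if pe > ps:
                self._promoter_trees.setdefault(g.chrom, IntervalTree()).addi(ps, pe, g.gene_id)
            utr5: list[GenomicInterval] = []
            utr3: list[GenomicInterval] = []
            cds: list[GenomicInterval] = []
            for tx in g.transcripts:
                if tx.cds:
                    cds.extend(tx.cds)
                    u5, u3 = tx.utr_intervals()  # type: ignore[misc]
                    utr5.extend(u5)
                    utr3.extend(u3)
            self._features[g.gene_id] = {
                "5UTR": tuple(utr5),
                "3UTR": tuple(utr3),
                "CDS": tuple(cds),
                "exon_union": g.exon_union,
            }

    def overlapping_genes(self, interval: GenomicInterval) -> list[Gene]:
        tree = self._span_trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return [self.genes[h.data] for h in sorted(hits, key=lambda h: (h.begin, h.data))]

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[h.data] for h in sorted(tree.at(pos), key=lambda h: h.data)]

    def in_promoter(self, chrom: str, pos: int) -> bool:
        tree = self._promoter_trees.get(chrom)
        return bool(tree is not None and tree.at(pos))

    def in_feature(self, gene_id: str, label: str, chrom: str, pos: int) -> bool:
        if label == "other_exon":
            ivs = self._features[gene_id]["exon_union"]
        else:
            ivs = self._features[gene_id][label]
        return any(iv.contains(chrom, pos) for iv in ivs)


def assign_peaks(
    peaks: Sequence[Peak],
    genes: Iterable[Gene] | AnnotationIndex,
    min_fraction: float = 0.5,
    use_exon_union: bool = False,
) -> list[PeakAssignment]:
    """Assign each peak to every gene holding >= ``min_fraction`` of it.

    The fraction is the peak length inside the gene span (the default,
    inclusive threshold); with ``use_exon_union`` the fraction is computed
    against the gene's merged exons instead.  Unassignable peaks are
    simply absent from the output.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError(f"min_fraction {min_fraction} outside (0, 1]")
    index = genes if isinstance(genes, AnnotationIndex) else AnnotationIndex(genes)
    out: list[PeakAssignment] = []
    for peak in peaks:
        for gene in index.overlapping_genes(peak.interval):
            exon_ov = intersect_length(peak.interval, gene.exon_union)
            if use_exon_union:
                ov = exon_ov
            else:
                ov = overlap_length(peak.interval, gene.span)
            fraction = ov / peak.length
            if fraction >= min_fraction:
                out.append(PeakAssignment(peak, gene.gene_id, fraction, exon_ov))
    return out


def categorize_peak(
    peak: Peak,
    genes: Iterable[Gene] | AnnotationIndex,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    promoter_window: int = 2000,
) -> str:
    """Single feature label for a peak, decided by its summit.

    The summit (midpoint when unknown) is tested against each class in
    ``precedence`` order; the first class containing it wins.  UTR and CDS
    labels require CDS annotation on at least one transcript; exonic
    summits of CDS-less genes fall to ``other_exon``.
    """
    unknown = set(precedence) - set(FEATURE_LABELS)
    if unknown or len(set(precedence)) != len(FEATURE_LABELS):
        raise ValueError(f"precedence must be a permutation of {FEATURE_LABELS}; got {tuple(precedence)}")
    index = genes if isinstance(genes, AnnotationIndex) else AnnotationIndex(genes, promoter_window)
    s = peak.summit
    chrom = peak.interval.chrom
    spanning = index.genes_at(chrom, s)
    for label in precedence:
        if label == "intergenic":
            return "intergenic"
        if label == "promoter":
            if index.in_promoter(chrom, s):
                return "promoter"
        elif label == "intron":
            if any(not index.in_feature(g.gene_id, "other_exon", chrom, s) for g in spanning):
                return "intron"
        else:
            if any(index.in_feature(g.gene_id, label, chrom, s) for g in spanning):
                return label
    return "intergenic"


def region_proportions(
    peaks: Sequence[Peak],
    genes: Iterable[Gene] | AnnotationIndex,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    promoter_window: int = 2000,
) -> dict[str, float]:
    """Fraction of peaks per feature category, plus an ``exon`` aggregate.

    ``exon`` = 5UTR + CDS + 3UTR + other_exon.  The seven category
    proportions sum to 1; the aggregate is reported alongside them.
    """
    if not peaks:
        raise ValueError("region_proportions: empty peak list")
    index = genes if isinstance(genes, AnnotationIndex) else AnnotationIndex(genes, promoter_window)
    counts = {label: 0 for label in FEATURE_LABELS}
    for p in peaks:
        counts[categorize_peak(p, index, precedence)] += 1
    n = len(peaks)
    props = {label: c / n for label, c in counts.items()}
    props["exon"] = props["5UTR"] + props["CDS"] + props["3UTR"] + props["other_exon"]
    return props


def metagene_position(peak: Peak, transcript: Transcript) -> Optional[float]:
    """Summit position scaled onto a 5'UTR/CDS/3'UTR metagene axis.

    The summit is mapped to the spliced transcript coordinate and scaled
    piecewise into [0,1) for the 5'UTR, [1,2) for the CDS and [2,3) for
    the 3'UTR.  Returns None when the transcript lacks CDS annotation or
    the summit is not exonic in this transcript.
    """
    if not transcript.cds:
        logger.debug("transcript %s lacks CDS annotation", transcript.transcript_id)
        return None
    pos = transcript.spliced_position(peak.summit)
    if pos is None:
        return None
    u5, u3 = transcript.utr_lengths()  # type: ignore[misc]
    c = transcript.cds_length
    if pos < u5:
        return pos / u5
    if pos < u5 + c:
        return 1.0 + (pos - u5) / c
    return 2.0 + (pos - u5 - c) / u3 if u3 > 0 else 3.0 - 1e-9


def metagene_table(
    peaks: Sequence[Peak],
    genes: Iterable[Gene] | AnnotationIndex,
    min_fraction: float = 0.5,
    bins: int = 30,
) -> tuple[list[float], np.ndarray]:
    """Metagene positions for assigned peaks plus a binned density.

    Each peak is scaled on the longest transcript of every gene it is
    assigned to (consistent with the score's longest-transcript
    normalisation).  Returns the positions and a ``bins``-bin density
    histogram over [0, 3).
    """
    index = genes if isinstance(genes, AnnotationIndex) else AnnotationIndex(genes)
    positions: list[float] = []
    for a in assign_peaks(peaks, index, min_fraction=min_fraction):
        pos = metagene_position(a.peak, index.genes[a.gene_id].longest_transcript)
        if pos is not None:
            positions.append(pos)
    hist, _ = np.histogram(positions, bins=bins, range=(0.0, 3.0), density=True)
    return positions, hist
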