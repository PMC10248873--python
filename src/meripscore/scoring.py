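"""Per-gene m6A scores.

For a gene g with assigned peaks p (methylation level m_p, length len_p)
and longest-transcript spliced length L, the score is

    length_weighted (default):  S_g = sum_p m_p * len_p / L
    product (literal reading):  S_g = (sum_p m_p) * (sum_p len_p) / L

Both modes coincide for single-peak genes.  The exon-restricted variant
replaces each peak's length term by the bp of the peak inside the gene's
merged exons, dropping fully intronic peaks.

A gene with no assigned peak in a sample is *absent* from the score
table, not zero: absence encodes "not methylated", which the replicate
screening criteria need to be decidable.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assign import AnnotationIndex, PeakAssignment, assign_peaks
from .model import Gene, Peak

logger = logging.getLogger(__name__)

__all__ = ["SCORE_MODES", "gene_score", "exon_gene_score", "score_table"]

SCORE_MODES = ("length_weighted", "product")


def _check(assignments: Sequence[PeakAssignment], L: int, mode: str) -> None:
    if mode not in SCORE_MODES:
        raise ValueError(f"unknown score mode {mode!r}; expected one of {SCORE_MODES}")
    if L <= 0:
        raise ValueError(f"longest-transcript length must be positive, got {L}")
    if len({a.gene_id for a in assignments}) > 1:
        raise ValueError("assignments span multiple genes")
    for a in assignments:
        if a.peak.signal < 0:
            raise ValueError(f"negative methylation level on peak {a.peak.name}")


def _aggregate(pairs: list[tuple[float, int]], L: int, mode: str) -> float:
    if not pairs:
        return 0.0
    if mode == "length_weighted":
        return sum(m * ln for m, ln in pairs) / L
    return sum(m for m, _ in pairs) * sum(ln for _, ln in pairs) / L


def gene_score(assignments: Sequence[PeakAssignment], L: int, mode: str = "length_weighted") -> float:
    """m6A score of one gene in one sample from its peak assignments."""
    _check(assignments, L, mode)
    return _aggregate([(a.peak.signal, a.peak.length) for a in assignments], L, mode)


def exon_gene_score(assignments: Sequence[PeakAssignment], L: int, mode: str = "length_weighted") -> float:
    """Exon-restricted m6A score: peak lengths replaced by exonic overlap.

    Peaks with no exonic overlap are dropped entirely (they contribute to
    neither sum in either mode).
    """
    _check(assignments, L, mode)
    pairs = [(a.peak.signal, a.exon_overlap) for a in assignments if a.exon_overlap > 0]
    return _aggregate(pairs, L, mode)


def score_table(
    peaks_by_sample: Mapping[tuple[str, str], Sequence[Peak]],
    genes: Iterable[Gene] | AnnotationIndex,
    min_fraction: float = 0.5,
    mode: str = "length_weighted",
    use_exon_union: bool = False,
) -> pd.DataFrame:
    """Score every (gene, sample) pair with at least one assigned peak.

    ``peaks_by_sample`` maps (group, replicate) to that sample's peaks.
    Returns a DataFrame with columns gene_id, group, replicate, score,
    exon_score, n_peaks, L — one row per methylated (gene, sample); genes
    without peaks in a sample are absent, not zero-filled.
    """
    if not peaks_by_sample:
        raise ValueError("score_table: no samples given")
    index = genes if isinstance(genes, AnnotationIndex) else AnnotationIndex(genes)
    rows = []
    for (group, replicate), peaks in peaks_by_sample.items():
        by_gene: dict[str, list[PeakAssignment]] = {}
        for a in assign_peaks(peaks, index, min_fraction=min_fraction, use_exon_union=use_exon_union):
            by_gene.setdefault(a.gene_id, []).append(a)
        for gene_id in sorted(by_gene):
            L = index.genes[gene_id].longest_transcript.length
            asn = by_gene[gene_id]
            rows.append(
                {
                    "gene_id": gene_id,
                    "group": group,
                    "replicate": replicate,
                    "score": gene_score(asn, L, mode),
                    "exon_score": exon_gene_score(asn, L, mode),
                    "n_peaks": len(asn),
                    "L": L,
                }
            )
    if not rows:
        logger.warning("score_table: no peak was assignable to any gene")
        return pd.DataFrame(columns=["gene_id", "group", "replicate", "score", "exon_score", "n_peaks", "L"])
    df = pd.DataFrame(rows)
    if df.duplicated(["gene_id", "group", "replicate"]).any():
        raise RuntimeError("internal error: duplicate (gene, sample) rows")
    return df
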