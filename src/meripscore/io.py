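"""File I/O: GTF, narrowPeak/BED6, bedGraph, GMT.

GTF is 1-based closed; everything internal is 0-based half-open, so starts
are shifted by -1 on read and +1 on write.  narrowPeak/BED/bedGraph are
already 0-based half-open and pass through unchanged.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

from .model import CoverageTrack, Gene, GenomicInterval, Peak, Transcript

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_gtf",
    "write_gtf",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "read_gmt",
    "write_annotation_summary",
]


class ParseError(ValueError):
    """A malformed line in an input file, reported with its line number."""


def read_gtf(path: str | Path) -> list[Gene]:
    """Assemble genes from the exon (and CDS) lines of a GTF file.

    Only ``exon`` and ``CDS`` features are consumed; each must carry
    ``gene_id`` and ``transcript_id`` attributes.  Transcripts that end up
    with no exons (e.g. a bare ``transcript`` line) are skipped with a
    warning.  Genes are returned sorted by gene_id.
    """
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    cds: dict[str, list[GenomicInterval]] = defaultdict(list)
    tx_gene: dict[str, str] = {}
    seen_tx: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            ftype = feat.featuretype
            if ftype in ("transcript", "mRNA"):
                # record the transcript id so exon-less transcripts can be warned about
                try:
                    seen_tx.add(feat.attributes["transcript_id"][0])
                except KeyError:
                    pass
                continue
            if ftype not in ("exon", "CDS"):
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ParseError(f"{path}: line {lineno}: missing attribute {exc}") from exc
            if feat.start > feat.end:
                raise ParseError(f"{path}: line {lineno}: start > end")
            # GTF 1-based closed -> 0-based half-open
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            seen_tx.add(tx_id)
            prev = tx_gene.setdefault(tx_id, gene_id)
            if prev != gene_id:
                raise ParseError(
                    f"{path}: line {lineno}: transcript {tx_id} assigned to both "
                    f"{prev} and {gene_id}"
                )
            (exons if ftype == "exon" else cds)[tx_id].append(iv)

    transcripts: dict[str, list[Transcript]] = defaultdict(list)
    for tx_id in sorted(seen_tx):
        if tx_id not in exons:
            logger.warning("transcript %s has no exon lines; skipped", tx_id)
            continue
        gene_id = tx_gene[tx_id]
        transcripts[gene_id].append(
            Transcript(tx_id, gene_id, tuple(exons[tx_id]), tuple(cds.get(tx_id, ())))
        )
    genes = [Gene(gid, tuple(txs)) for gid, txs in sorted(transcripts.items())]
    if not genes:
        logger.warning("no genes assembled from %s", path)
    return genes


def write_gtf(genes: Iterable[Gene], path: str | Path, source: str = "meripscore") -> None:
    """Write genes back to GTF (gene/transcript/exon/CDS lines)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
            span = gene.span
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for tx in gene.transcripts:
                tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                ts = tx.span
                fh.write(
                    f"{gene.chrom}\t{source}\ttranscript\t{ts.start + 1}\t{ts.end}\t.\t"
                    f"{gene.strand}\t.\t{tattrs}\n"
                )
                for exon in tx.exons:
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{gene.strand}\t.\t{tattrs}\n"
                    )
                for c in tx.cds:
                    fh.write(
                        f"{gene.chrom}\t{source}\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{gene.strand}\t0\t{tattrs}\n"
                    )


def read_narrowpeak(path: str | Path, group: str = "", replicate: str = "") -> list[Peak]:
    """Read peaks from narrowPeak (BED6+4) or plain BED6.

    The peak methylation level is narrowPeak column 7 (signalValue); for
    6-column BED it falls back to column 5 (score).  Peaks are strandless:
    column 6 is ignored.  The summit offset comes from column 10 when
    present (-1 = unknown).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) not in (6, 10):
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 (BED) or 10 (narrowPeak) columns, got {len(f)}"
                )
            try:
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if end <= start:
                raise ParseError(f"{path}: line {lineno}: end <= start")
            if len(f) == 10:
                signal = float(f[6])
                qv = float(f[8])
                q_value = qv if qv >= 0 else None
                summit = int(f[9])
            else:
                signal = float(f[4])
                q_value = None
                summit = -1
            if signal < 0:
                raise ParseError(f"{path}: line {lineno}: negative signal {signal}")
            try:
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, start, end),
                        signal=signal,
                        group=group,
                        replicate=replicate,
                        summit_offset=summit,
                        q_value=q_value,
                        name=name,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if not peaks:
        logger.warning("no peaks read from %s", path)
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as 10-column narrowPeak (signal in column 7)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i + 1}"
            q = -1.0 if p.q_value is None else p.q_value
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{name}\t0\t.\t"
                f"{p.signal:.6g}\t-1\t{q:.6g}\t{p.summit_offset}\n"
            )


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a bedGraph coverage file into a :class:`CoverageTrack`."""
    segments: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            try:
                segments[f[0]].append((int(f[1]), int(f[2]), float(f[3])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return CoverageTrack(segments)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, members per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns (name, description, genes)")
            sets[f[0]] = {g for g in f[2:] if g}
    return sets


def write_annotation_summary(genes: Iterable[Gene], path: str | Path) -> None:
    """TSV summary: gene_id, n_transcripts, longest_transcript_id, L."""
    with open(path, "w") as fh:
        fh.write("gene_id\tn_transcripts\tlongest_transcript_id\tL\n")
        for g in sorted(genes, key=lambda g: g.gene_id):
            lt = g.longest_transcript
            fh.write(f"{g.gene_id}\t{len(g.transcripts)}\t{lt.transcript_id}\t{lt.length}\n")
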