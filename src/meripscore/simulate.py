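"""Synthetic MeRIP-seq data with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a compact annotation on one synthetic chromosome; peaks placed on
methylated genes with summits biased toward CDS and 3'UTR; log-normal
peak enrichment signals; multiplicative log-normal replicate noise (so
signals stay positive and fold-change screening is exercised naturally);
and a knockout group in which a chosen subset of genes carries a
multiplicative m6A increase.  Unmethylated genes emit no peaks,
exercising the "absent means unmethylated" semantics of the score table.

Everything is deterministic given the config seed; annotation and peak
generation draw from independent substreams, so either can be re-run
alone.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .model import Gene, GenomicInterval, Peak, Transcript

__all__ = ["SimConfig", "SimTruth", "simulate_annotation", "simulate_peaks", "write_simulation", "write_flat_bedgraph"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters (all lengths in bp, signals unitless).

    Defaults describe a small but realistic two-group, two-replicate
    MeRIP experiment: 500 genes of 3-6 exons, 40% of genes methylated
    with on average 2 peaks each, MACS2-like fold enrichments
    LogNormal(ln 10, 0.5), summit placement biased 10/50/40 toward
    5'UTR/CDS/3'UTR, a 10% subset of methylated genes doubled in the
    knockout group, and 0.2 log-scale replicate noise.
    """

    n_genes: int = 500
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (200, 1500)
    utr_fraction: tuple[float, float] = (0.15, 0.35)  # (5', 3') fractions of transcript
    two_transcript_prob: float = 0.3
    peak_len: tuple[int, int] = (150, 400)
    peak_rate: float = 2.0
    methylated_fraction: float = 0.4
    signal_logmean: float = math.log(10.0)
    signal_logsd: float = 0.5
    region_bias: tuple[float, float, float] = (0.1, 0.5, 0.4)  # (5'UTR, CDS, 3'UTR)
    effect_fraction: float = 0.1
    effect_size: float = 2.0
    replicate_sd: float = 0.2
    seed: int = 0
    chrom: str = "chrS"
    groups: tuple[str, str] = ("WT", "KO")
    ko_group: str = "KO"
    replicates: tuple[str, ...] = ("rep1", "rep2")

    def __post_init__(self) -> None:
        for name in ("methylated_fraction", "effect_fraction", "two_transcript_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.methylated_fraction):
            raise ValueError("methylated_fraction must be positive")
        if self.effect_size <= 0:
            raise ValueError(f"effect_size must be positive, got {self.effect_size}")
        if self.replicate_sd < 0:
            raise ValueError(f"replicate_sd must be non-negative, got {self.replicate_sd}")
        if sum(self.utr_fraction) >= 0.9:
            raise ValueError("UTR fractions leave too little CDS")
        if any(w < 0 for w in self.region_bias) or sum(self.region_bias) <= 0:
            raise ValueError("region_bias weights must be non-negative and not all zero")
        for name in ("exons_per_gene", "exon_len", "intron_len", "peak_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) infeasible")
        if self.ko_group not in self.groups:
            raise ValueError(f"ko_group {self.ko_group!r} not among groups {self.groups}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth: per-gene methylation and knockout-effect status."""

    genes: pd.DataFrame  # gene_id, methylated, is_effect, true_delta

    @property
    def effect_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["is_effect"], "gene_id"])

    @property
    def methylated_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["methylated"], "gene_id"])


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def _spliced_to_genomic(exons: Sequence[GenomicInterval], lo: int, hi: int) -> list[GenomicInterval]:
    """Genomic intervals for the left-to-right spliced range [lo, hi)."""
    out: list[GenomicInterval] = []
    offset = 0
    for e in exons:
        a, b = max(lo, offset), min(hi, offset + e.length)
        if a < b:
            out.append(GenomicInterval(e.chrom, e.start + (a - offset), e.start + (b - offset), e.strand))
        offset += e.length
    return out


def simulate_annotation(config: SimConfig) -> list[Gene]:
    """Generate non-overlapping genes with UTR/CDS segmentation.

    Each gene has one full-length transcript (the longest, carrying the
    CDS) and, with probability ``two_transcript_prob``, a shorter isoform
    missing a terminal exon.
    """
    rng = _rng(config, 1)
    genes: list[Gene] = []
    cursor = 1000
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gid = f"g{i + 1:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons: list[GenomicInterval] = []
        pos = cursor
        for j in range(n_exons):
            elen = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            exons.append(GenomicInterval(config.chrom, pos, pos + elen, strand))
            pos += elen
            if j < n_exons - 1:
                pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
        L = sum(e.length for e in exons)
        # segmentation in left-to-right spliced coordinates; on the minus
        # strand the 5'UTR sits at the genomic right
        u5 = max(1, int(round(config.utr_fraction[0] * L)))
        u3 = max(1, int(round(config.utr_fraction[1] * L)))
        left_cut, right_cut = (u5, u3) if strand == "+" else (u3, u5)
        cds = _spliced_to_genomic(exons, left_cut, L - right_cut)
        transcripts = [Transcript(f"{gid}.t1", gid, tuple(exons), tuple(cds))]
        if n_exons >= 2 and rng.random() < config.two_transcript_prob:
            drop_first = rng.random() < 0.5
            sub = tuple(exons[1:]) if drop_first else tuple(exons[:-1])
            transcripts.append(Transcript(f"{gid}.t2", gid, sub))
        genes.append(Gene(gid, tuple(transcripts)))
        cursor = pos + int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
    return genes


def _region_extents(gene: Gene) -> dict[str, tuple[GenomicInterval, ...]]:
    tx = gene.longest_transcript
    u5, u3 = tx.utr_intervals()  # type: ignore[misc]
    return {"5UTR": u5, "CDS": tx.cds, "3UTR": u3}


def simulate_peaks(
    genes: Sequence[Gene],
    config: SimConfig,
) -> tuple[dict[tuple[str, str], list[Peak]], SimTruth]:
    """Generate per-sample peak sets and the ground truth behind them.

    Per methylated gene, max(Poisson(peak_rate), 1) peaks share geometry
    and base signal across all samples; the knockout effect multiplies
    the group-level signal of effect genes by ``effect_size``, and each
    (peak, sample) draws independent exp(Normal(0, replicate_sd^2))
    noise.
    """
    rng = _rng(config, 2)
    gene_ids = [g.gene_id for g in genes]
    n_meth = int(round(config.methylated_fraction * len(genes)))
    n_eff = int(round(config.effect_fraction * len(genes)))
    if n_eff > n_meth:
        raise ValueError(
            f"effect_fraction ({config.effect_fraction}) exceeds methylated_fraction "
            f"({config.methylated_fraction}): effect genes must be methylated to be observable"
        )
    methylated = set(rng.choice(gene_ids, size=n_meth, replace=False))
    effect = set(rng.choice(sorted(methylated), size=n_eff, replace=False))

    samples = [(g, r) for g in config.groups for r in config.replicates]
    peaks: dict[tuple[str, str], list[Peak]] = {s: [] for s in samples}
    for gene in genes:
        if gene.gene_id not in methylated:
            continue
        regions = _region_extents(gene)
        weights = np.array(config.region_bias, dtype=float)
        labels = ("5UTR", "CDS", "3UTR")
        avail = np.array([sum(iv.length for iv in regions[lab]) > 0 for lab in labels])
        w = np.where(avail, weights, 0.0)
        w = w / w.sum()
        k = max(int(rng.poisson(config.peak_rate)), 1)
        for j in range(k):
            label = labels[int(rng.choice(3, p=w))]
            ivs = regions[label]
            lens = np.array([iv.length for iv in ivs], dtype=float)
            iv = ivs[int(rng.choice(len(ivs), p=lens / lens.sum()))]
            summit = int(rng.integers(iv.start, iv.end))
            plen = int(rng.integers(config.peak_len[0], config.peak_len[1] + 1))
            left = int(round(plen * rng.uniform(0.3, 0.7)))
            start = max(0, summit - left)
            end = start + plen
            base = float(rng.lognormal(config.signal_logmean, config.signal_logsd))
            for group, rep in samples:
                delta = config.effect_size if (group == config.ko_group and gene.gene_id in effect) else 1.0
                noise = math.exp(rng.normal(0.0, config.replicate_sd)) if config.replicate_sd > 0 else 1.0
                peaks[(group, rep)].append(
                    Peak(
                        GenomicInterval(gene.chrom, start, end),
                        signal=base * delta * noise,
                        group=group,
                        replicate=rep,
                        summit_offset=summit - start,
                        name=f"{gene.gene_id}_p{j + 1}",
                    )
                )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "methylated": [g in methylated for g in gene_ids],
            "is_effect": [g in effect for g in gene_ids],
            "true_delta": [config.effect_size if g in effect else 1.0 for g in gene_ids],
        }
    )
    return peaks, SimTruth(truth)


def write_simulation(
    outdir: str | Path,
    config: SimConfig,
    genes: Optional[Sequence[Gene]] = None,
    peaks: Optional[dict[tuple[str, str], list[Peak]]] = None,
    truth: Optional[SimTruth] = None,
) -> dict[str, Path]:
    """Write GTF, per-sample narrowPeak files, truth TSV and config snapshot.

    Generates anything not passed in.  Returns a name -> path map; file
    contents are byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genes is None:
        genes = simulate_annotation(config)
    if peaks is None or truth is None:
        peaks, truth = simulate_peaks(genes, config)
    paths: dict[str, Path] = {}
    paths["gtf"] = outdir / "annotation.gtf"
    mio.write_gtf(genes, paths["gtf"])
    for (group, rep), plist in peaks.items():
        key = f"peaks_{group}_{rep}"
        paths[key] = outdir / f"{key}.narrowPeak"
        mio.write_narrowpeak(plist, paths[key])
    paths["truth"] = outdir / "truth.tsv"
    truth.genes.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = outdir / "sim_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def write_flat_bedgraph(
    path: str | Path,
    chrom: str,
    length: int,
    base_depth: float = 0.0,
    segments: Sequence[tuple[int, int, float]] = (),
) -> None:
    """Write a flat bedGraph with optional constant-depth segments.

    A minimal coverage emitter for exercising signal recomputation from
    IP/input tracks; segments override the base depth on their extent.
    """
    boundaries = sorted({0, length} | {s for s, _, _ in segments} | {e for _, e, _ in segments})
    seg_list = sorted(segments)
    with open(path, "w") as fh:
        for a, b in zip(boundaries, boundaries[1:]):
            depth = base_depth
            for s, e, d in seg_list:
                if s <= a and b <= e:
                    depth = d
            fh.write(f"{chrom}\t{a}\t{b}\t{depth:.6g}\n")
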