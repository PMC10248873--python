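"""Shared fixtures: hand-built toy annotation and peak sets.

All fixtures are constructed programmatically so expected values can be
derived by hand next to the asserts that use them.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from meripscore import Gene, GenomicInterval, Peak, Transcript

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_peak(chrom: str, start: int, end: int, signal: float = 1.0, summit: int = -1, **kw) -> Peak:
    return Peak(GenomicInterval(chrom, start, end), signal=signal, summit_offset=summit, **kw)


@pytest.fixture
def two_isoform_gene() -> Gene:
    """g1 on chr1(+): t1 = exons [100,200)+[300,350) (len 150), t2 = [100,500) (len 400)."""
    t1 = Transcript("t1", "g1", (GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 300, 350, "+")))
    t2 = Transcript("t2", "g1", (GenomicInterval("chr1", 100, 500, "+"),))
    return Gene("g1", (t1, t2))


@pytest.fixture
def coding_gene() -> Gene:
    """gA on chr1(+): exons [1000,1400)+[1600,2000), CDS [1100,1400)+[1600,1800).

    Spliced length 800; segmentation 5'UTR=100, CDS=500, 3'UTR=200.
    """
    tx = Transcript(
        "gA.t1",
        "gA",
        (GenomicInterval("chr1", 1000, 1400, "+"), GenomicInterval("chr1", 1600, 2000, "+")),
        (GenomicInterval("chr1", 1100, 1400, "+"), GenomicInterval("chr1", 1600, 1800, "+")),
    )
    return Gene("gA", (tx,))


@pytest.fixture
def minus_coding_gene() -> Gene:
    """gB on chr1(-): exon [3000,3400), CDS [3100,3300); 5'UTR is the genomic right."""
    tx = Transcript(
        "gB.t1",
        "gB",
        (GenomicInterval("chr1", 3000, 3400, "-"),),
        (GenomicInterval("chr1", 3100, 3300, "-"),),
    )
    return Gene("gB", (tx,))
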