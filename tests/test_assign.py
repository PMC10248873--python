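"""Peak-to-gene assignment, feature categories and metagene scaling."""

import numpy as np
import pytest

from meripscore import (
    AnnotationIndex,
    Gene,
    GenomicInterval,
    Transcript,
    assign_peaks,
    categorize_peak,
    metagene_position,
    region_proportions,
)
from .conftest import make_peak


def span_gene(gene_id: str, chrom: str, start: int, end: int, strand: str = "+") -> Gene:
    tx = Transcript(f"{gene_id}.t1", gene_id, (GenomicInterval(chrom, start, end, strand),))
    return Gene(gene_id, (tx,))


class TestAssignPeaks:
    def test_admitted_at_sixty_percent(self):
        genes = [span_gene("g", "chr1", 0, 220)]
        (a,) = assign_peaks([make_peak("chr1", 100, 300)], genes)
        assert a.gene_id == "g"
        assert a.overlap_fraction == pytest.approx(0.6)

    def test_rejected_just_below_half(self):
        genes = [span_gene("g", "chr1", 0, 199)]
        assert assign_peaks([make_peak("chr1", 100, 300)], genes) == []

    def test_inclusive_boundary_at_exactly_half(self):
        genes = [span_gene("g", "chr1", 0, 200)]
        (a,) = assign_peaks([make_peak("chr1", 100, 300)], genes)
        assert a.overlap_fraction == pytest.approx(0.5)

    def test_multi_gene_assignment(self):
        genes = [span_gene("gA", "chr1", 0, 220), span_gene("gB", "chr1", 50, 400)]
        out = assign_peaks([make_peak("chr1", 100, 300)], genes)
        by_gene = {a.gene_id: a.overlap_fraction for a in out}
        assert by_gene == {"gA": pytest.approx(0.6), "gB": pytest.approx(1.0)}

    def test_exon_overlap_against_union(self, two_isoform_gene):
        # exon union of g1 is [100, 500); peak [50, 250) overlaps 150 bp of it
        (a,) = assign_peaks([make_peak("chr1", 50, 250)], [two_isoform_gene])
        assert a.exon_overlap == 150

    def test_brute_force_oracle_on_random_configurations(self):
        """Per-base membership counting is the independent oracle for the 50% rule."""
        rng = np.random.default_rng(5)
        for trial in range(500):
            gene_bounds = []
            genes = []
            for gi in range(rng.integers(1, 4)):
                s = int(rng.integers(0, 800))
                e = s + int(rng.integers(50, 400))
                gene_bounds.append((f"g{gi}", s, e))
                genes.append(span_gene(f"g{gi}", "chr1", s, e))
            ps = int(rng.integers(0, 1000))
            peak = make_peak("chr1", ps, ps + int(rng.integers(10, 300)))
            expected = set()
            bases = set(range(peak.interval.start, peak.interval.end))
            for gid, s, e in gene_bounds:
                if len(bases & set(range(s, e))) / peak.length >= 0.5:
                    expected.add(gid)
            got = {a.gene_id for a in assign_peaks([peak], genes)}
            assert got == expected, f"trial {trial}"


class TestCategorizePeak:
    def test_summit_in_cds(self, coding_gene):
        p = make_peak("chr1", 1150, 1250, summit=50)  # summit at 1200, inside CDS
        assert categorize_peak(p, [coding_gene]) == "CDS"

    def test_summit_in_utrs(self, coding_gene):
        assert categorize_peak(make_peak("chr1", 1000, 1100, summit=50), [coding_gene]) == "5UTR"
        assert categorize_peak(make_peak("chr1", 1850, 1950, summit=50), [coding_gene]) == "3UTR"

    def test_minus_strand_utr_orientation(self, minus_coding_gene):
        # gB(-): genomic right of the CDS is the 5'UTR
        assert categorize_peak(make_peak("chr1", 3300, 3400, summit=50), [minus_coding_gene]) == "5UTR"
        assert categorize_peak(make_peak("chr1", 3000, 3100, summit=50), [minus_coding_gene]) == "3UTR"

    def test_promoter_window_upstream_strand_aware(self, coding_gene, minus_coding_gene):
        assert categorize_peak(make_peak("chr1", 400, 600, summit=100), [coding_gene]) == "promoter"
        assert categorize_peak(make_peak("chr1", 3400, 3500, summit=50), [minus_coding_gene]) == "promoter"

    def test_intron_and_intergenic(self, coding_gene):
        assert categorize_peak(make_peak("chr1", 1450, 1550, summit=50), [coding_gene]) == "intron"
        assert categorize_peak(make_peak("chr1", 50000, 50100, summit=50), [coding_gene]) == "intergenic"

    def test_exonic_summit_without_cds_annotation(self, two_isoform_gene):
        assert categorize_peak(make_peak("chr1", 150, 250, summit=10), [two_isoform_gene]) == "other_exon"

    def test_midpoint_fallback_when_summit_unknown(self, coding_gene):
        assert categorize_peak(make_peak("chr1", 1150, 1250), [coding_gene]) == "CDS"

    def test_bad_precedence_rejected(self, coding_gene):
        with pytest.raises(ValueError, match="precedence"):
            categorize_peak(make_peak("chr1", 0, 10), [coding_gene], precedence=("CDS", "intron"))


class TestRegionProportions:
    def test_counting_with_exon_aggregate(self, coding_gene):
        peaks = [
            make_peak("chr1", 1150, 1250, summit=50),  # CDS
            make_peak("chr1", 1200, 1300, summit=50),  # CDS
            make_peak("chr1", 1450, 1550, summit=50),  # intron
            make_peak("chr1", 50000, 50100, summit=50),  # intergenic
        ]
        props = region_proportions(peaks, [coding_gene])
        assert props["CDS"] == pytest.approx(0.5)
        assert props["intron"] == pytest.approx(0.25)
        assert props["intergenic"] == pytest.approx(0.25)
        assert props["exon"] == pytest.approx(0.5)

    def test_degenerate_single_category(self, coding_gene):
        props = region_proportions([make_peak("chr1", 1150, 1250, summit=50)] * 3, [coding_gene])
        assert props["CDS"] == 1.0
        assert props["exon"] == 1.0

    def test_categories_sum_to_one(self, coding_gene, minus_coding_gene):
        rng = np.random.default_rng(3)
        peaks = [make_peak("chr1", int(s), int(s) + 100, summit=50) for s in rng.integers(0, 5000, 40)]
        props = region_proportions(peaks, [coding_gene, minus_coding_gene])
        total = sum(v for k, v in props.items() if k != "exon")
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_peaks_error(self, coding_gene):
        with pytest.raises(ValueError):
            region_proportions([], [coding_gene])


class TestMetagenePosition:
    def test_segment_boundaries_and_scaling(self, coding_gene):
        tx = coding_gene.transcripts[0]
        # summit exactly at CDS start (genomic 1100, spliced 100) -> 1.0
        assert metagene_position(make_peak("chr1", 1100, 1200, summit=0), tx) == pytest.approx(1.0)
        # halfway through the 3'UTR: spliced 700 = genomic 1900 -> 2.5
        assert metagene_position(make_peak("chr1", 1900, 1950, summit=0), tx) == pytest.approx(2.5)
        # middle of the 5'UTR: spliced 50 -> 0.5
        assert metagene_position(make_peak("chr1", 1050, 1100, summit=0), tx) == pytest.approx(0.5)

    def test_intronic_summit_is_none(self, coding_gene):
        assert metagene_position(make_peak("chr1", 1450, 1550, summit=50), coding_gene.transcripts[0]) is None

    def test_cds_less_transcript_is_none(self, two_isoform_gene):
        tx = two_isoform_gene.transcripts[0]
        assert metagene_position(make_peak("chr1", 150, 250, summit=10), tx) is None

    def test_monotone_along_transcript(self, coding_gene):
        """Summits ordered 5'->3' map to non-decreasing scaled positions."""
        tx = coding_gene.transcripts[0]
        summits = list(range(1000, 1400, 25)) + list(range(1600, 2000, 25))
        positions = [metagene_position(make_peak("chr1", s, s + 10, summit=0), tx) for s in summits]
        assert all(p is not None for p in positions)
        assert all(a <= b for a, b in zip(positions, positions[1:]))
        assert all(0 <= p < 3 for p in positions)

    def test_monotone_on_minus_strand(self, minus_coding_gene):
        tx = minus_coding_gene.transcripts[0]
        summits = range(3000, 3400, 20)  # genomic order = 3'->5' on minus strand
        positions = [metagene_position(make_peak("chr1", s, s + 5, summit=0), tx) for s in summits]
        assert all(a >= b for a, b in zip(positions, positions[1:]))
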