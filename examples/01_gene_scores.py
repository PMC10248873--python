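"""Score two genes from a handful of peaks.

Builds a two-gene annotation and one sample of three peaks in memory,
assigns peaks to genes under the 50%-overlap rule and prints the
per-gene m6A scores: each gene's score is the sum of (peak signal x
peak length) over its peaks, divided by the spliced length of its
longest transcript, so a score of 1 means "one transcript-length worth
of unit-level methylation".
"""

from meripscore import Gene, GenomicInterval, Peak, Transcript, score_table

genes = [
    Gene("Ddx3y", (
        Transcript("Ddx3y.t1", "Ddx3y", (GenomicInterval("chr1", 1_000, 2_000, "+"),)),
        Transcript("Ddx3y.t2", "Ddx3y", (GenomicInterval("chr1", 1_000, 2_500, "+"),)),
    )),
    Gene("Uty", (
        Transcript("Uty.t1", "Uty", (GenomicInterval("chr1", 5_000, 6_000, "-"),)),
    )),
]

peaks = {("WT", "rep1"): [
    Peak(GenomicInterval("chr1", 1_100, 1_400), signal=8.0, name="p1"),   # Ddx3y, 300 bp
    Peak(GenomicInterval("chr1", 2_100, 2_300), signal=5.0, name="p2"),   # Ddx3y (t2 span), 200 bp
    Peak(GenomicInterval("chr1", 5_200, 5_500), signal=12.0, name="p3"),  # Uty, 300 bp
]}

table = score_table(peaks, genes)
print(table.to_string(index=False))
print()
print("Ddx3y: (8*300 + 5*200) / 1500 =", (8 * 300 + 5 * 200) / 1500, "(L = longest isoform, 1500 bp)")
print("Uty:   12*300 / 1000        =", 12 * 300 / 1000)
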