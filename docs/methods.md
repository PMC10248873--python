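# Methods

## Coordinates and data model

All intervals are internally 0-based half-open on named chromosomes;
GTF's 1-based closed convention is converted at the file boundary in
both directions, so a read–write round trip reproduces the original
coordinates. A single convention internally removes the usual
off-by-one bug class. Peaks are strandless regardless of their BED
strand column: MeRIP peak calling runs on unstranded fragment coverage,
so strand information is meaningful only on the gene side. "Transcript
length" always means spliced (mature-transcript) length — the sum of
exon lengths — because the score normalises an mRNA-level quantity;
genomic span would conflate intron content with transcript size.
Longest-transcript ties break to the lexicographically smallest
transcript id for determinism.

## Peak-to-gene assignment

A peak is assigned to every gene whose span contains at least
`min_fraction` (default 0.5, inclusive) of the peak's length. Peaks are
the unit of m6A modification here, so "half of the modification inside
the gene" is read as a length fraction; the summit is deliberately not
used for admission because a summit-based rule discards the extent
information the score needs. The fraction is computed against the gene
span by default; an exon-union base is available
(`use_exon_union=True`) for annotations where spans are dominated by
very long introns. Multi-gene assignment is allowed — overlapping genes
each count the peak — because the selection is defined per gene, not as
a partition of peaks. The exonic overlap of each assignment is computed
against the gene's merged exons across all isoforms.

## The gene m6A score

The score aggregates peak methylation levels normalised by the longest
transcript length L. Two aggregation modes exist because the defining
sentence of the statistic is ambiguous between them:

- `length_weighted` (default): S = Σ m_p·len_p / L. Each peak
  contributes its level weighted by its own extent; this is a proper
  weighted aggregate and is linear in the signals.
- `product`: S = (Σ m_p)(Σ len_p) / L, the most literal reading of
  "level multiplied by the summed lengths".

Both coincide for single-peak genes; on equal-length peaks product
dominates length_weighted (Chebyshev's sum inequality). All downstream
stages are mode-agnostic. The exon-restricted score substitutes each
peak's exonic overlap for its length and drops fully intronic peaks
from both factors; under `length_weighted` it is bounded above by the
whole-gene score.

The per-peak level m_p defaults to narrowPeak signalValue (the caller's
fold enrichment). `compute_peak_signal` optionally recomputes it from
IP and input bedGraph tracks, either as max(0, mean IP − mean input) —
the IP-minus-input "abundance" one reads off a browser track — or as a
ratio with pseudo-count 1. Which definition a given study used is
rarely recoverable; exposing both as modes keeps the choice explicit.

## Screening and differential comparison

Screening per group keeps genes methylated in both replicates with
score strictly > `score_min` (default 1) in both replicates and
replicate fold change max/min strictly < `fc_max` (default 2).
"Score above the minimum in *both* replicates" is the default reading
(`score_rule="both"`); `"either"` is available. Fold change as max/min
is symmetric in replicate order and ≥ 1 by construction. The group
score is the arithmetic mean of the two replicate scores — the simplest
unbiased combiner. Screening is idempotent, and the retained set
shrinks monotonically in `score_min` and grows monotonically in
`fc_max`.

The group comparison is two-sided Wilcoxon. The default is the
unpaired rank-sum over the two groups' screened score distributions
(the construction behind the usual violin-plot comparison of two
different-sized gene sets); the paired signed-rank over the screened
gene intersection is available and is the more powerful choice when the
signal is concentrated in a minority of genes — a 10% effect fraction
shifts the pooled distribution's AUC by only a few percent, which the
unpaired test cannot distinguish from null at a few hundred genes,
while the paired test sees the affected genes' differences directly at
the top of the rank order. The end-to-end recovery evaluation therefore
uses the signed-rank variant for its power check and reports the
rank-sum p alongside. Exact enumeration is used whenever both sample
sizes are ≤ 25 and the data are untied; otherwise the tie-corrected
normal approximation with continuity correction.

The exon-increased differential set contains genes screened (on exon
scores) in both groups with KO group score strictly greater than WT;
genes screened only in KO can be added with `include_ko_only` (default
off, since presence in one group alone cannot show an increase). No
per-gene significance testing is attempted — the selection is by
direction, matching how such sets are defined in practice.

## Enrichment

Over-representation is the hypergeometric upper tail P(X ≥ k) with
BH step-up adjustment across collections (via
`statsmodels.multipletests`). The recommended universe is the set of
m6A-modified genes (any assigned peak in either group): testing a
subset of methylated genes against the whole annotation would conflate
"methylated at all" with the contrast of interest. No set-size filters
are applied by default. GO hierarchies are out of scope; collections
are user-supplied GMT.

## Feature categories and metagene

A peak's single category is decided by its summit (midpoint when the
caller reported none) tested in precedence order, default
5'UTR > 3'UTR > CDS > other_exon > promoter > intron > intergenic —
UTR/CDS before generic exon so segmentation is used when available,
genic classes before promoter so a summit inside one gene is not
claimed by a neighbour's promoter. The promoter is 2 kb upstream of the
gene span's TSS, strand-aware; 2 kb is the common annotator default, as
no window is otherwise dictated. Metagene positions map the summit to
the spliced coordinate of the gene's longest transcript (consistent
with the score's normaliser) and scale piecewise into [0,1) for the
5'UTR, [1,2) for the CDS, [2,3) for the 3'UTR; transcripts without CDS
annotation yield no position.

## Synthetic data

The generator produces what the analysis consumes, with truth:

- Geometry: `n_genes` (default 500) non-overlapping genes on one
  synthetic chromosome, 3–6 exons of 120–300 bp separated by 200–1500 bp
  introns, intergenic gaps drawn from the intron range. One chromosome
  suffices since nothing downstream depends on chromosome count. Each
  gene has a full-length CDS-bearing transcript (5'UTR/CDS/3'UTR at
  15/50/35% of spliced length — a 3'-heavy split typical of mRNA) and,
  with probability 0.3, a shorter isoform missing a terminal exon.
- Peaks: 40% of genes methylated (a typical detected fraction in MeRIP
  experiments) with max(Poisson(2), 1) peaks each; summit regions drawn
  with bias (0.1, 0.5, 0.4) over 5'UTR/CDS/3'UTR, mirroring the CDS- and
  3'UTR-dominated m6A topology; peak lengths 150–400 bp (MACS2-like
  widths on fragmented libraries); base signals LogNormal(ln 10, 0.5)
  (fold enrichments centred near 10).
- Effects and noise: a 10% subset of genes — drawn from the methylated
  genes, since an effect on an unmethylated gene would be unobservable —
  has its KO group signal multiplied by δ = 2; every (peak, sample)
  draws independent exp(N(0, σ²)) noise with σ = 0.2. Multiplicative
  log-normal noise keeps signals positive and exercises the fold-change
  screen naturally.
- Determinism: annotation and peaks derive from independent substreams
  of the config seed; identical configs give byte-identical GTF and
  narrowPeak output.

What the generator does *not* emulate: read-level sampling noise (peak
boundaries are exact, not re-called), between-gene expression
differences confounding IP enrichment, antibody off-target binding, or
peak-calling artefacts near gene boundaries. Passing the recovery tests
therefore shows the pipeline's arithmetic and selection logic are
correct under the assumed noise model, not that any particular
biological dataset would yield these sensitivities.

A structural note on recovery metrics: with direction-only selection
(KO > WT, strict), every screened null gene is a false positive with
probability exactly 1/2, because its WT and KO group scores are
exchangeable. Precision is therefore bounded near
T/(T + 0.5·M₀) where T is the number of true effect genes and M₀ the
screened null genes — about 0.4 under the default composition (50
effect vs ~150 methylated null genes). Raising precision requires a
magnitude threshold on the KO/WT ratio (the ratio is emitted in the
differential table for exactly this purpose), not a different
implementation of the selection.

## Numerical choices

- Strict inequalities at the screening boundaries (score = 1 rejected,
  FC = 2 rejected), matching "greater than" / "less than" semantics.
- Exact Wilcoxon enumeration only for untied data at n ≤ 25; ties force
  the corrected normal approximation at any n.
- Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, …)`, p clipped
  to 1.
- Zero paired differences are dropped before the signed-rank test; all
  zeros is an error ("no informative pairs").
- Degenerate inputs: empty peak files and empty score tables warn and
  propagate as empty; an empty universe or query in enrichment is an
  error; a peak extending outside a coverage track's recorded extent is
  an error naming the peak (silence is indistinguishable from missing
  data there).

## Problem sizes

Tests and the acceptance script run at desk scale: 500–1000 simulated
genes, ≤ ~1300 peaks per sample, 1000 null datasets of 200 genes per
group for the calibration check, full enumeration oracles only for
universes ≤ 25 and samples ≤ 7. The complete suite runs in a few
seconds on one CPU.
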