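# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open. BED input/output is native;
GTF (1-based, inclusive) is converted on read. A gene's TSS is its
strand-oriented 5′ end: `tx_start` on the + strand, `tx_end − 1` on the −
strand. Signed TSS distances are in gene orientation — 0 at the TSS base,
positive downstream into the gene body — so + and − strand genes pool into one
histogram. Each gene model carries a single transcript; collapsing alternative
TSSs to a major one is the caller's responsibility.

## Genome partitioning

`partition_genome` assigns every base exactly one label, so per-label bp
totals sum to the genome length by construction. Where classes overlap
(within a gene, or between genes), precedence is fixed:
promoter > 5′UTR > coding exon > intron > 3′UTR > 3′ flank > intergenic.
Promoter outranks everything because promoter occupancy is the analysis'
central readout; an annotation source rarely specifies how such conflicts
should resolve, so the rule is explicit here. Promoter = `flank_width` bp
upstream of the TSS, 3′ flank = `flank_width` bp downstream of the gene end
(default 5000 bp, configurable). Genes without CDS annotation contribute all
exonic bases as coding exon and no UTR classes — a deliberate degenerate-input
rule rather than a guess. The implementation paints per-class interval sets
from lowest to highest precedence over per-chromosome label arrays; tests
compare it base-by-base against an independent brute-force labeler.

## Peak filtering

The FDR cutoff comes from an independent ChIP-qPCR validation table binned by
FDR range: scanning bins in increasing FDR, the cutoff is the upper bound of
the last bin in the maximal prefix whose validation rates all reach
`min_validation_rate` (default 0.8). This is a formalization of
validation-driven cutoff choice; no published algorithm exists for it, so the
rule is documented rather than assumed. Filtering is inclusive (FDR ≤ cutoff).

## Enrichment statistics

Feature enrichment counts each peak once, at its midpoint (bp-composition mode
is available and is the default for repeat composition, which is a sequence
fraction, not a peak count). Significance per class is the two-sided exact
binomial test with the class's genome fraction as null probability. Two
caveats are intentional: (i) in bp mode the bases of one peak are not
independent draws, so bp-mode p-values are optimistic and the ratio is the
primary readout; (ii) raw p-values can underflow double precision — reported
p is clamped at the smallest positive double and `log10_p` is the
authoritative quantity.

Peak–gene density regression is ordinary least squares (statsmodels), with
per-covariate simple R² alongside the multiple regression; collinear designs
are flagged and their t-test p-values withheld. Overlap with HOT regions
reports both the fraction of peaks with ≥ 1 bp overlap and the bp Jaccard
index of the merged interval sets.

## TSS analysis

A peak's position is its midpoint; its TSS distance is the signed distance to
the nearest TSS, ties in absolute distance broken toward the downstream
(positive) side, deterministically. Histogram bins are half-open
`[lo, lo + bin_width)`; a peak exactly at +window falls in the last bin, so
the histogram total equals the count of peaks with |distance| ≤ window.
H3K4me3 co-occurrence is ≥ 1 shared bp with any K4 peak, no minimum overlap
fraction, among peaks within ±1 kb of a TSS.

## Binding–expression integration

Two bound-gene definitions coexist deliberately. AbG sets use peak-midpoint
distance to the TSS within a window (±5/±1/±0.5 kb; nested by construction).
The positional scan instead asks, at each 1-bp offset d, whether a peak
*interval covers* TSS + d — windows attribute binding to a gene, the scan
attributes it to a position. Responsive sets use strict thresholds
(fold change > 1.2 or < 1/1.2, p < 0.05); the expression file header must
declare linear vs log2 fold change, never sniffed. The universe is the
intersection of annotated and measured genes; both set tests and the scan use
the exact hypergeometric upper tail, with p = 1 by convention at offsets where
no gene is bound. The scan reports raw per-offset p-values — neighboring
offsets are strongly dependent (a 1 kb peak covers 1000 consecutive offsets),
so a per-offset multiplicity correction would be misleading; the argmin and
its p are the summary statistics. Ties in the minimum resolve to the smallest
offset.

## miRNA target sites

Target prediction is seed complementarity only: the DNA match motif is the
reverse complement of the miRNA seed (default 7mer-m8 = positions 2–8; 6mer
and 8mer-with-A-anchor rules available), scanned on both strands, overlapping
occurrences all counted, `N` never matching. This is a transparent stand-in
for heavier context-scoring predictors, and the seed rule is configurable
precisely because site definitions differ between tools.

Matched controls are one interval per peak — same chromosome, identical
length, uniform position, rejected if overlapping any excluded interval
(default: the peaks themselves) — fully determined by the RNG seed. GC
matching within a tolerance is available but off by default, since length
matching is the defining constraint. Because peak and control sets are
length-matched pairwise, total sequence scanned is equal, and under the null
each site falls in either set with probability ½: per-miRNA significance is
the two-sided exact binomial test of the peak-set count against
Binomial(total, ½), Benjamini–Hochberg-corrected across miRNAs. Calls require
both the adjusted p < α and the ratio cutoff (≥ 1.5 enriched, ≤ 1/1.5
depleted); zero sites in both sets is neutral with p = 1.

Motif discovery enumerates all k-mers (k = 6) over the input set plus every
merge of two observed k-mers differing at exactly one position (two-letter
IUPAC code there), and returns the candidate contained in the most sequences,
ties broken by total occurrences then lexicographically. Homology to a
reference hexamer is ungapped positionwise identity, maximized over the
consensus' concrete variants.

## Synthetic data generator

The generator emits the complete input bundle with ground truth. Default
conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| genome | 6 chromosomes × 500 kb | several chromosomes for per-chromosome statistics; small enough for per-base labeling |
| genes | 150, graded per-chromosome density (weights 0.5→2.0) | gene-dense vs gene-poor chromosomes, so peak density co-varies with gene density and the regression is estimable |
| gene structure | 2–5 exons, 2–4 kb, UTRs = 30% of terminal exons | exercises every feature class |
| active fraction | 0.5 | half the genes carry marks/peaks |
| peaks | 60 TSS-proximal + 60 background, 1 kb each | typical ChIP peak size ~1 kb; background exercises the intergenic classes |
| TSS offsets | Normal(0, 400 bp) | concentrates peaks within ±1 kb of TSSs |
| FDRs | TSS peaks U(0, 0.05); background 50% U(0, 0.05) / 50% U(0.06, 0.9) | filtering is exercised — some peaks fail any sensible cutoff |
| validation table | rates 0.95 / 0.58 / 0.17 over (0, 0.05, 0.2, 1.0) | selects cutoff 0.05 at min rate 0.8 |
| H3K4me3 | at each active TSS with probability 0.9, 1.5 kb | co-occurrence parameter recoverable from the costratification |
| repeats | 15% of genome; SINE-heavy class mix | repeat composition has signal without dominating |
| expression | log2FC ~ Normal(0, 0.25); genes whose peak covers TSS+100 get −0.6 | knockdown downregulates promoter-bound genes; p-values are the two-sided normal tail of the observed log2FC, so effect genes mostly pass the 1.2-fold / 0.05 thresholds |
| miRNAs | 30 random 22-mers; implants into peak sequences at rate 0.9, drawn from the first 5 miRNAs | a small target subset with real enrichment, the rest null |

Each output draws from its own RNG stream derived from the master seed
(`default_rng([seed, stream_id])`), so adding an output never perturbs the
others; the bundle is byte-identical across runs of the same seed.

What the generator does **not** emulate: realistic nucleotide composition
(uniform ACGT, so GC% hovers near 50 and GC-driven confounding is absent),
read-level noise (peaks are exact intervals, not pileups), overlapping genes
and alternative TSSs, repeat-derived sequence (repeat intervals are labels
over random sequence, so repeat classes carry no sequence signal), and
realistic peak-count scales (~10² peaks vs ~10⁴ in a real experiment). Passing
tests therefore demonstrate correctness of the statistical machinery and
recoverability of implanted effects at toy scale — not performance on real
data, where annotation quality and sequence composition add failure modes the
generator cannot produce.

## Numerical and design notes

- Problem sizes in tests (genome ≤ 50 kb for brute-force equivalence, 1000
  label permutations, 200 null miRNA replicates, 50 scan-recovery replicates)
  are the package's chosen trade-off between statistical resolution and a test
  suite that runs in seconds to a few minutes.
- The hypergeometric calibration check uses N = 5000, |A| = |B| = 1500: with
  smaller, coarser sets the exact test's attainable level sits visibly below
  the nominal 0.05 purely from discreteness, which would test the band, not
  the implementation.
- Peak BED output uses `%.17g` floats so write→read round-trips are exact.
- Degenerate inputs have defined behavior throughout: empty gene list (all
  intergenic), no peaks (spacing sentinel `None`), zero denominator in
  co-occurrence (`None` fraction), no validation bin passing (`NO_CUTOFF`
  sentinel), zero sites in both miRNA sets (neutral, p = 1), controls
  impossible to place (error naming the peak after a bounded number of
  attempts).
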