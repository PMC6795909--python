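# Methods

## Scope and data model

The package analyses a genes × samples expression matrix over four germline
populations (premeiotic I, meiotic II/III, postmeiotic IV) with replicates,
plus a gene annotation giving each gene a chromosome (2, 3, X, Y, other),
coordinates and an FPKM length. Chromosome arms (2L/2R, 3L/3R) collapse to
their chromosome; the *A. gambiae* Y is a set of contigs, so any sequence
name starting with "Y" (or listed explicitly) maps to Y. Coordinates are
1-based inclusive. FPKM is computed as counts × 10⁹ / (length ×
per-sample total); for GFF3 input the length is the union of exon spans
when exons are annotated, otherwise the genomic span — FPKM definitions
vary on this point, so the choice is explicit. Replicates are collapsed to
per-population profiles by the arithmetic mean of FPKM; upstream alignment
and counting are out of scope.

## Expression thresholds and presence

"Expressed" means FPKM strictly above the threshold (default 10 FPKM), so
a gene exactly at the cut-off is not expressed and threshold 0 means "all
genes with any expression". The global filter keeps genes expressed in at
least one population; per-population presence uses the same threshold by
default (configurable separately), and the 15 Venn regions partition the
filtered genes exactly.

## Bootstrap median-ratio analysis

For each population and threshold, genes enter by that population's FPKM
(strict inequality). The observed ratio divides the numerator chromosome's
median (X, or chromosome 2 for the control) by the denominator median (all
autosomal genes, or chromosome 3). Only the numerator set is resampled —
with replacement, at its observed size, 10,000 times — and each bootstrap
median is divided by the fixed observed denominator median; the 95% CI is
the 2.5th/97.5th percentile of those ratios. Resampling both sides is
available behind a flag. Measured over 200 synthetic datasets in which the
X is the scaled autosomal distribution, the CI covers the generative ratio
~91–95% of the time: slightly below nominal because denominator sampling
variability is not resampled, which is acceptable at autosomal gene counts
(≥ 2,000) where that term is small.

Quantiles use linear interpolation (numpy's default, type 7); medians of
even-sized sets are midpoints. Sweeps derive one RNG sub-seed per
(population, numerator, threshold) combination from the root seed, so
results are independent of sweep order and identical seeds reproduce CIs
to the last digit. Degenerate cells (empty side, zero denominator median)
are skipped and reported, not fatal. All ratios, CIs and rank-test
p-values are invariant to a common rescaling of the FPKM matrix.

The Wilcoxon rank-sum test between consecutive populations treats the two
populations' per-gene FPKM vectors as independent samples (matching the
classical test), two-sided; the exact null distribution is used for
tie-free samples up to n = 25, otherwise the tie-corrected normal
approximation.

## Tissue specificity

τ = Σᵢ(1 − x̂ᵢ)/(N − 1) with x̂ᵢ = xᵢ/max(x). The index is scale-invariant,
bounded in [0, 1], and monotone under concentrating mass into the maximal
tissue. All-zero genes get a missing τ (they can never be enriched), and a
tie at the maximum is an ambiguous maximum — never enriched. The
enrichment cut-off τ ≥ 0.8 is inclusive.

## Stage-resolved analysis

Z-profiles are (t − mean)/sd of t = log₂(FPKM+1) with the population-count
(ddof 0) denominator; constant profiles map to the zero vector. k-means
uses k-means++ starts, best of 10 initialisations, and a mandatory seed;
cluster labels are canonicalised by centroid peak position (ties broken by
the centroid value at stage I) so runs are label-comparable. The default
k = 10 matches the number of stage programs the analysis is designed to
separate.

The differential-expression stage is deliberately pluggable: the built-in
surrogate is a one-way F-test across populations on log₂(FPKM+1)
replicate values (zero-variance genes flagged missing), calibrated on null
simulations to a 3–7% type-I rate at α = 0.05; a per-gene p-value table
from a count-based tool can replace it verbatim. Benjamini–Hochberg
adjustment is applied downstream. The enrichment rule — FPKM_p/(FPKM_q+ε)
> 2 for every other population q, adjusted p < 0.05, max FPKM > 1 — can
select at most one population per transcript since the fold cut-off
exceeds 1. The fold-change map uses ε = 0.01 FPKM in numerator and
denominator (the data contain exact zeros and no convention is standard;
ε is configurable), masks transcripts below 1 FPKM everywhere or with
adjusted p > 0.05, and orders transcripts by chromosome then start.

## Synthetic data generator

The generator emulates the study design, not any particular dataset: gene
counts 1,000/1,000/350/10 on chromosomes 2/3/X/Y (echoing the X's paucity
of male-germline genes), four populations × three replicates, a log-normal
expression baseline (ln-scale σ = 1.2, heavy-tailed like real FPKM) with a
20% near-zero "dropout" fraction, and ten stage-program archetypes
(single-stage peaks, plateaus, ramps, ends-high) multiplying the baseline.
Sex-linked genes are hemizygous (x_dosage = 0.5), optionally compensated
in population I (factor c ≥ 1), and silenced from stage II onward by a
per-population schedule (defaults 0.25/0.1/0.1 for II/III/IV, echoing the
relative collapse of X-linked medians across stages); ~1% of X genes are
escapees, exempt from silencing and given a meiotic-peaked program so
their III-vs-I fold change is positive. Replicate noise is multiplicative
log-normal at CV 0.2.

Population-level mean FPKM is normalised so Σ FPKM·length_kb = 10⁶, the
identity a real FPKM table satisfies; fragment counts are then Poisson
(negative-binomial behind a flag) around FPKM × length_kb ×
library_size/10⁶ at a 3×10⁷-fragment library, so recomputing FPKM from
counts inverts the generator in expectation. A consequence of simulating
a small genome is that per-gene FPKM values are larger than in a full
transcriptome; ratio, τ and clustering results are scale-invariant, and
thresholds retain their published values. The companion tissue-panel
generator plants single-tissue genes (5% by default) on a broadly
expressed background across six tissues including testis and ovary.

What the generator does **not** emulate: read-level noise and mapping
artefacts, gene-length biases in counting, correlated expression along
chromosomes, isoform structure, and between-replicate library-composition
effects beyond the global FPKM normalisation. Passing tests therefore
demonstrate that the statistics recover planted structure under the
stated noise model, not that any specific biological dataset would yield
particular values.

## Problem sizes and determinism

Default analyses run at the generator's native sizes (2,360 genes, 12
samples, 10,000 bootstrap replicates) in seconds. Multi-dataset checks
(parameter recovery over 20 seeds, CI coverage over 200 datasets) use the
same sizes; stochastic point estimates quoted against analytic
expectations are means over 20 independently seeded datasets, since a
single dataset's median ratio carries ~7% sampling noise at 350 X genes.
Every stochastic routine takes an explicit seed; the pipeline derives all
stage seeds from one root seed and rerunning an identical configuration
reproduces all outputs byte-for-byte.

## Known limitations

- The bootstrap CI is percentile-based and numerator-only; it slightly
  undercovers when the denominator set is small.
- The F-test surrogate assumes approximately log-normal replicate noise;
  strongly overdispersed counts warrant an external count-model p-value
  table (supported as a drop-in input).
- Y-linked genes follow the same hemizygous/silencing factors as the X;
  the package does not model Y-specific amplification or multi-copy gene
  families, and no Y ratio analysis is offered.
- Tissue-panel simulation is a stand-in for a real multi-tissue atlas;
  genes absent from a real panel should be supplied as missing and emerge
  with missing τ.
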