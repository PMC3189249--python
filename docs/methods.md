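# Methods

`promethylome` implements a desk-scale analysis of promoter DNA methylation
measured by MeDIP-chip: methylated DNA is immunoprecipitated, hybridised to
a promoter tiling array against an input (whole genomic DNA) channel, and
the enrichment of each probe is turned into region-level methylation calls
that are then compared across a developmental panel — ES cells, ES-derived
germ layers (ectoderm, endoderm, paraxial mesoderm), adult somatic tissues
(brain, liver, skeletal muscle) and mature sperm, with testis entering only
through expression data. Because the pipeline's statistical behaviour can
only be verified against a known answer, the package ships a first-class
synthetic-data generator that plants a methylome with the structure this
kind of study exhibits and lets every downstream stage be scored against
the planted truth.

## Probe scoring

Arrays carry log2 intensities. Each array is standardised robustly:
median-centred and divided by 1.4826 × MAD, the normal-consistent robust
scale. For a sample with MeDIP replicates *M₁…M_R* and input replicates
*I₁…I_R*, each probe contributes the per-replicate differences
*M_r − mean(I)*. The score of probe *i* pools these differences over all
probes whose centre lies within ± `window_bp`/2 (default 800 bp, chosen to
capture one tiling neighbour on each side at the ~354 bp default probe
spacing; a smaller window leaves every window below the minimum value
count), and computes

  score(i) = trimmed mean (trim `trim_frac` = 0.1 per tail) × √(effective count).

Windows with fewer than `min_probes` = 4 values yield a missing score.
Multiplying by √count makes the null variance of the score independent of
how many values a window holds, which is what lets an input-label-swap
null track (one pseudo-replicate instead of two, hence half the values per
window) sit on exactly the same scale as the observed track.

The consistent-MAD scale (rather than raw unit MAD) is deliberate: it puts
the null score standard deviation near 0.75, so the fixed call thresholds
2.5/3.0 sit at ≈3.3σ/4σ and per-probe false positives stay rare enough for
region-level precision; with raw-MAD scaling the same thresholds sit near
2.4σ and false calls at array scale (≈10⁵ probes per sample) overwhelm the
region set.

## Empirical FDR

FDR%(s) = 100 × min(1, #null ≥ s / #observed ≥ s), with the null track
scored from an input-vs-input label swap of the same sample. The curve is
regularised to be non-increasing in the threshold by a running minimum
over ascending thresholds; thresholds with no observed calls are reported
missing. Because the observed track's MAD absorbs a little genuine signal,
the estimate is mildly conservative when signal is present; on a
signal-free dataset estimate and realised false-positive fraction agree.

## Region calling

Per sample, maximal runs of probes scoring > 2.5 separated by ≤
`max_gap_bp` (300 bp, just above one probe gap) become intervals; intervals
from all samples are merged wherever they overlap (touching endpoints do
not merge). Each merged region is scored per sample by its maximum member
probe score and gated twice: region CpG density (mean of member-probe
500-bp window densities) must exceed 5%, and at least one sample must
exceed the high-confidence threshold 3.0. Within surviving regions the
per-sample call is tri-state: > 2.5 methylated, < 1.5 hypomethylated,
otherwise (including the boundary values and missing scores)
indeterminate.

## Cross-sample analysis

* **TSS profile** — probes carry strand-aware offsets to their gene's TSS;
  per 250-bp bin the frequency is (#probes scoring > 2.5)/(#probes), with a
  positional moving-average smoother (200 bp) that is the identity on a
  constant profile.
* **Zone tables** — region midpoints are assigned to the nearest TSS
  (strand-aware; ties to the lower gene id) and to a zone: core
  −1 kb..+0.5 kb (inclusive), tss_up upstream, tss_down downstream. Two
  core windows co-exist on purpose: zone tables use −1 kb..+0.5 kb, while
  gene-level methylation flags use the wider −1.5 kb..+0.5 kb core
  promoter; both are configurable.
* **Commonality** — each region is classified with explicit precedence:
  all_positive (methylated everywhere incl. sperm) > sperm-unconstrained
  positive (methylated in every non-sperm sample) > somatic_common
  (methylated in all germ layers and adult tissues) > early_diff_only
  (methylated in all germ layers, hypomethylated in all adult tissues) >
  variable; regions whose decisive (somatic) states include an
  indeterminate call and match nothing are reported unclassifiable.
* **T-DMRs** — regions with ≥1 methylated and ≥1 hypomethylated sample;
  indeterminate samples count for neither side.

## Enrichment

Genes are ranked by testis specificity: testis expression divided by the
maximum somatic expression, with both numerator and denominator floored at
1.0 on the mean-100-normalised scale so scores are strictly positive; ties
break on gene id. The gene set tested is the commonly methylated set —
genes of regions methylated (> 2.5) in every somatic sample within
CpG-gated regions that pass the 3.0 gate. Enrichment uses the weighted
Kolmogorov–Smirnov running sum (weight exponent 1; hits weighted by
|score|, misses decrement 1/(N−N_hit)), a gene-permutation null (default
1000 random same-size sets), add-one p-value smoothing on the matching
sign, and NES = ES / mean |null ES| of the same sign.

## Histone integration

Promoters are classified per sample into H3K4me3-only, H3K27me3-only,
bivalent, or neither, by ≥1 bp peak overlap with the closed TSS ± 2 kb
window. Gene-level methylation flags come from CMRs with a methylated
state whose midpoint falls in the core promoter. Cross-tabs report the
percentage of methylated genes per state; transition tables count the 16
ordered state pairs between two samples with destination-sample
methylation counts. Expression comparisons use Welch's t-test on
log2(signal + 1) with box-plot descriptives (median, quartiles, 10th/90th
percentiles).

## The synthetic study

One synthetic chromosome holds equally spaced gene slots (13 kb) with
random strands; each promoter is tiled by 25 probes spanning −6 kb..+2.5 kb
of the TSS (60 bp probes, ≈354 bp spacing). Sequence is generated with
background CpGs suppressed and CpG dinucleotides planted on a jittered
lattice at per-segment target densities — 8% in CpG-island cores and
planted CpG-rich regions, 4.2% in intermediate promoters, 2% in CpG-poor
planted regions, 1% background. Systematic (rather than Bernoulli)
placement keeps the realised window densities tightly around their
targets, so the low/intermediate/high promoter classes are cleanly
separated around the 4% and 5% analysis boundaries.

Planted methylome classes (fractions of genes, counts exact floors):
commonly methylated germline genes (4%; somatic level 0.9, ES/sperm 0.02,
testis-specific expression), ES+somatic methylated regions (2%;
everything but sperm — the pattern of constitutively methylated
reproductive gene clusters, which also gives the ES samples a realistic
methylation load), imprinting centres (1%; level 0.5 everywhere, relying
on enrichment saturation to score highly), single-germ-layer T-DMRs (3%;
10% maintained in the matched adult tissue), mosaically methylated gene
clusters (2%, blocks of 8 neighbours, each somatic sample methylated with
probability 0.8), and CpG-poor constitutively methylated promoters (15%,
removed by the 5% CpG gate by design). Planted regions are 2 kb wide and
sit in the core promoter with probability 0.08, otherwise uniformly in the
flanks with centre ranges extending past the probed span so that
methylation coverage is uniform out to the array edges; regions lying
(mostly) beyond the outermost probes cannot be recovered by any method and
are therefore excluded from recall denominators (≥3 probe centres inside
required).

Array signal: expected MeDIP log2 ratio = `enrichment_slope` (2.0) ×
methylation × c/(c + 10) for probe CpG count *c* per 500 bp — rising with
CpG density and saturating, so allele-methylated imprinted regions still
score above the high-confidence gate. Input arrays have zero expected
ratio. Noise is Gaussian on the log2 scale (σ = 0.25 per array, i.e.
lognormal multiplicative intensity noise), independent across replicate
arrays, on top of a shared per-probe affinity effect (σ = 0.40) that
cancels in the MeDIP-minus-input comparison.

Expression: per-gene log2 baselines (germline genes low everywhere, boosted
+3 log2 only in testis), a −2.5 log2 penalty wherever the planted region
overlaps the core promoter with level ≥ 0.5, then exact scaling of every
column to mean 100. Histone states are drawn conditionally on the
core-promoter methylation flag: unmethylated promoters are H3K4me3-marked
with probability 0.75 (bivalent 0.12, K27 0.03); methylated promoters
carry K4 with probability 0 by default — strict exclusivity, consistent
with K4 shielding promoters from de novo methylation — and are otherwise
bivalent (0.15), K27 (0.25) or unmarked. Peaks are emitted inside TSS ± 2 kb
for every assigned mark.

What the generator does **not** emulate: probe cross-hybridisation and
sequence-composition bias (the original tiling-array probe model), IVT
amplification bias, spatially correlated array artefacts, partial/bimodal
methylation levels, copy-number variation, or read-level histone data
(peaks are planted directly). Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the declared noise
model, not that the defaults are optimal for any particular real platform.

## Numerical and design choices

* Seeds: every stage draws from separately keyed `SeedSequence` children of
  one configuration seed; all outputs (including written tables) are
  byte-identical across reruns.
* Score windows never cross chromosome boundaries; probe windows truncated
  at sequence ends use the actual window length as density denominator.
* Boundary conventions: call thresholds are strict inequalities (2.5 and
  1.5 themselves are indeterminate); the HCP o/e 0.75 and GC 0.55 criteria
  are inclusive; zone boundaries (−1000, +500) are inclusive on both sides.
* Region score aggregation is the max member-probe score (peak-oriented);
  region density aggregation defaults to the mean of member-probe densities
  (`region_density_stat = "max"` is available).
* A region overlapping several promoters is assigned to the nearest TSS by
  midpoint; this choice is not forced by anything and is worth a
  sensitivity look on real data.
* Test scale: the default full-scale checks run at 5000 genes (≈125k
  probes, 36 arrays), where planted-class counts are large enough for the
  stochastic bounds (recall/precision ≥ 0.9, capture ≥ 0.95) to hold with
  wide margins across seeds.

## Known limitations

* The score is a re-specified windowed statistic in the spirit of
  model-based tiling-array scores, not a reimplementation of any published
  probe-sequence model; absolute score values are comparable only within
  this package.
* The empirical FDR is conservative in the presence of strong signal (the
  observed track's scale estimate absorbs some of it).
* Categories are assigned with precedence, so a region is counted exactly
  once even where definitions overlap.
* The histone transition analysis expects an ES-like reference sample; the
  K4-loss/methylation-gain correlation is not expected (and not asserted)
  between two differentiated samples.
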