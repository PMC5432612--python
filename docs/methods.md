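# Methods

## Overview

`paleoks` detects and dates paleopolyploidy (ancient whole-genome
duplication, WGD) from transcriptome-derived coding sequences. The chain of
inference is the classical one for Ks-based paleopolyploidy analysis:

1. cluster an all-vs-all protein similarity table into gene families;
2. estimate the synonymous divergence Ks of every within-species duplicate
   pair (a proxy for the age of the duplication);
3. filter and node-average the pair ages into a per-species age
   distribution;
4. separate the L-shaped small-scale-duplication (SSD) background from
   approximately Gaussian WGD bursts by normal-mixture modelling of
   ln(Ks), confirmed by a SiZer significance map;
5. convert the WGD peak to an absolute age with the molecular clock
   Ks = 2 T mu, where mu is a per-lineage synonymous rate calibrated from
   ortholog divergences at a fossil-constrained split.

A synthetic-data generator with a planted duplication history provides
ground truth for every stage, so the package's accuracy claims are backed
by parameter-recovery experiments that the test suite runs.

## Ks estimation (codonalign_ks)

Pairs are aligned at the protein level (global affine-gap dynamic
programming, BLOSUM62, gap open 10 / extend 1, end gaps penalized) and
back-mapped to codons, so gaps always occupy whole codons. Divergence is
estimated by Nei–Gojobori (1986) counting:

* synonymous *sites* per codon are the per-position fractions of
  single-nucleotide changes that preserve the amino acid, counting only
  sense-codon targets; S and N are averaged over the two sequences;
* *differences* per codon pair are averaged over all orders of the
  differing positions, excluding pathways through stop codons and
  renormalizing; if every pathway is blocked the column is skipped;
* columns containing gaps or ambiguity codes are skipped entirely;
* proportions are corrected with the Jukes–Cantor formula
  d = −(3/4) ln(1 − 4p/3); p ≥ 3/4 is reported as a saturation flag, never
  a number.

A counting estimator was chosen over a codon-model ML estimator because it
is exactly specifiable and exactly testable (the test suite checks it
against exhaustive pathway enumeration), and because in the Ks ≤ 2 window
that age-distribution analyses retain, NG86 and ML estimates agree
closely. The estimator sits behind a small interface so an ML variant can
be added without touching the rest of the pipeline.

## Family clustering (gene_families)

Hits are filtered at E-value ≤ 1e-10 and identity ≥ 40% (both inclusive —
the inclusive convention is pinned for reproducibility), self-hits
dropped, and reciprocal hits merged keeping the better bitscore. Families
come from Markov clustering (MCL) of the weighted graph with self-loops of
weight equal to the maximum incident weight, inflation 1.5 (the common
default for ortholog-group clustering), pruning at 1e-12, and convergence
when the maximum elementwise change falls below 1e-6 (at most 200
iterations). This is a deliberate simplification of OrthoMCL's full
reciprocal-best-hit normalization: at desk scale the symmetric
max-bitscore weighting followed by MCL recovers the same partitions, and
the simulator's truth-table check keeps it honest.

## Age distribution (age_distribution)

Four filters, applied in a fixed order with per-rule provenance counts:

1. **TE removal** — any pair with a transposable-element-flagged gene is
   dropped (transposition-derived duplicates are not genome duplications).
2. **Zero-Ks removal** — pairs with Ks ≤ 1e-9 are treated as the same
   transcript split by assembly (floating-point equality would be
   meaningless); in the family stage the two genes are merged before node
   averaging.
3. **Node averaging** — an m-member family contributes m−1 values, the
   average-linkage (UPGMA) merge heights of its pairwise Ks matrix; each
   merge height is exactly the mean of the cross-cluster pairwise values,
   which prevents a family of m similar-aged duplicates from contributing
   C(m,2) copies of one age.
4. **Saturation cut** — node values above Ks = 2.0 (inclusive boundary:
   exactly 2.0 is kept) or derived from saturated pairs are dropped;
   beyond 2 the estimator is noise-dominated.

**Mixture model.** Normal mixtures are fitted to x = ln(Ks) — WGD bursts
are approximately Gaussian on the log scale and the multiplicative error
of Ks estimates argues for log space. For k = 1..5, EM runs from 20 seeded
initializations (means at spread quantiles with jitter, pooled variance,
equal weights), converging when the log-likelihood gain drops below 1e-8
(at most 500 iterations); the log-likelihood is asserted non-decreasing at
every step, and a variance floor sigma ≥ 1e-4 guards against component
collapse. Restarts follow the em-EM short-run strategy: each initialization is
burned in for 25 iterations and only the best continues to full
convergence — the restarts differ only in initialization jitter, so the
short runs rank them reliably at a fraction of the cost. Model selection
minimizes BIC = −2 ll + (3k−1) ln n. The
reported peak is exp(mu_log), the back-transformed median — stabler than
the log-normal mode and mean. Components with peak below Ks = 0.1 are
classified as the SSD-dominated initial peak and excluded from WGD
candidacy, as are components with weight < 0.05. The SSD background is
absorbed by those low components rather than fitted as an explicit
exponential; a hybrid exponential+normal likelihood would add parameters
the data cannot separate. When several components qualify as WGD
signatures, the *dating* step uses the heaviest-weight one: the background
occasionally leaks a small component just above the 0.1 boundary, and the
dominant Gaussian is the burst of interest.

**SiZer.** For each bandwidth h (20 log-spaced in [0.02, 0.5]) and
position x (0..2, step 0.02), the Gaussian-kernel density-derivative
estimate is the mean of per-observation terms −(x−X_i)/h³ φ((x−X_i)/h);
its standard error is the sample standard deviation of the terms divided
by √n. A pointwise 95% CI classifies each cell INCREASING / DECREASING /
FLAT, overridden by SPARSE where the effective sample size
Σ K_h(x−X_i)/K_h(0) is below 5 (the Chaudhuri–Marron rule). No across-grid
multiplicity adjustment is applied — the map is read qualitatively, as a
confirmation that a mixture peak's flanks are real, and the pointwise
convention is the configurable default.

## Dating (dating)

The mean ortholog-pair Ks between every species pair (over single-copy
orthogroups, saturated pairs skipped and counted) gives a distance matrix;
Saitou–Nei neighbor joining with lexicographic tie-breaking and
negative-branch clamping (deficit moved to the sibling) gives the Ks tree.
The per-lineage rate comes from one calibrated split: mu = Ks / (2 × age),
with the age taken from the calibration file (point age if given,
interval midpoint otherwise). The WGD age is T = peak_Ks / (2 mu). The
interval maps peak_ks ± 1.96 × SE through the same formula, where
SE(peak_ks) is the delta-method image of the component mean's standard
error sigma_log/√(n·weight); it quantifies peak-location uncertainty only,
not calibration or rate uncertainty. Bayesian divergence dating is out of
scope — the clock inversion is the reproducible arithmetic of WGD dating,
and a relaxed-clock machinery would be a second method, not a feature.

## Enrichment (enrichment)

Fisher's exact test, two-sided by the point-probability method (all tables
with the observed margins whose hypergeometric probability does not exceed
the observed one), with the sample odds ratio a·d/(b·c). Adjustment is
Benjamini–Hochberg at 5% across all tested categories. Genes with no
annotation in the ontology count in the "rest" margin rather than being
dropped, so per-set totals equal the gene-list sizes; annotations are
taken flat, without ontology-graph ancestor closure.

## Synthetic data (synthetic_data)

The generator emulates transcriptome-derived CDS sets for five species on
an ultrametric tree (crown age 56.43 Mya; stem extends to 110 Mya so that
duplications older than the crown fall on the stem). Study conditions, as
defaults: a shared WGD at 75 Mya with retention probability 0.25, lineage
rate 2.5e-9 /site/yr, SSD birth rate 1.0 per gene per unit per-lineage Ks
thinned by survival probability exp(−age/0.2) (giving the L-shaped
exponential age background of continuous duplication and loss), 5%
TE-flagged families, gene lengths uniform in 100–300 codons, Ka/Ks = 0.2.

Sequence evolution places synonymous and nonsynonymous differences at
previously untouched positions until quotas Poisson(p_s·S) and
Poisson(p_n·N) are met, where p = (3/4)(1 − e^{−4d/3}) is the JC inverse
of the target distance; stop codons are never created. This makes the
NG86+JC estimator approximately unbiased for the planted distance by
construction (verified by Monte-Carlo tests: bias < 3% at Ks 0.4, < 10%
at Ks 1.5 where pathway reclassification and quota saturation bite).
There are no indels, no codon-usage bias and no among-site rate
heterogeneity, and the emitted hit table is truth-driven (an edge for
every true family pair, none across families) — so passing recovery tests
certify the statistical pipeline, not alignment or homology-search
robustness on real data. TE families are ordinary families carrying a
flag; the TE filter acts on annotation, not sequence.

The truth table records every within-family pair with its event class
(WGD / SSD / ORTHOLOG = the type of the pair's most recent common
duplication or speciation node) and true Ks = 2 mu t of that node.

## Problem sizes and numerical choices

Recovery experiments use 500 base genes over 5 species (roughly 3,500
genes, ~170 retained Ks values per species after filtering), 20 seeded
replicates for the end-to-end and mixture-recovery suites, and 80
subsampled orthogroups for the rate calibration (the mean ortholog Ks is
insensitive to the subsample). These sizes give stable recovery — the
dated WGD age lands within 10% of the planted 75 Mya in ≥ 18/20
replicates — while keeping a full run on a single CPU in minutes.

Degenerate inputs are errors, not silent results: alignments with no
usable codon column, pairs with zero synonymous sites, samples below 30
values for mixture/SiZer fitting, all-equal samples (variance floor), and
species pairs with no usable ortholog pair all raise with the offending
record named.

## Known limitations

* The NG86/JC estimator ignores transition/transversion bias and codon
  usage; peaks beyond Ks ≈ 1.5 are compressed relative to an ML estimator.
* Single calibrated rate: one mu per analysis (mirroring the standard
  single-rate usage); per-branch rates from the NJ tree are a flag away
  but not propagated into intervals.
* The WGD-age interval reflects mixture-peak uncertainty only.
* MCL on synthesized, truth-driven similarity graphs is easier than on
  real BLAST graphs; real-data family quality depends on the upstream
  search tool.
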