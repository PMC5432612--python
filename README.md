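# paleoks

Detect and date paleopolyploidy — ancient whole-genome duplication (WGD) —
from transcriptome-derived coding sequences, via duplicate-pair Ks age
distributions.

Continuous small-scale duplication (SSD) leaves an L-shaped, exponential
background in the distribution of synonymous divergences (Ks) between
duplicate gene pairs; a WGD leaves a burst of similar-aged pairs visible as
an approximately Gaussian peak on top of it. `paleoks` implements the full
chain of inference for this analysis:

* **Gene families** — all-vs-all protein hits (E ≤ 1e-10, identity ≥ 40%)
  clustered by Markov clustering (inflation 1.5); within-species duplicate
  pairs and single-copy ortholog groups extracted from the families.
* **Ks estimation** — protein-guided pairwise codon alignment (BLOSUM62,
  affine gaps) and Nei–Gojobori (1986) counting with pathway averaging and
  Jukes–Cantor correction, with explicit saturation flags.
* **Age distribution** — the standard filters (transposable-element pairs,
  Ks = 0 assembly artifacts, Ks > 2 saturation) and average-linkage
  *node averaging*, which collapses an m-copy family's C(m,2) pairwise ages
  to its m−1 duplication-node ages.
* **Peak calling** — EM-fitted normal mixtures on ln(Ks) with BIC model
  selection, and a SiZer map (SIgnificant ZERo crossings of the density
  derivative) to confirm peak flanks against background wiggles.
* **Dating** — the molecular clock Ks = 2 T μ: a mean ortholog-Ks distance
  matrix and neighbor-joining Ks tree calibrate the per-lineage synonymous
  rate μ at a fossil-constrained split, and the clock is inverted at the
  mixture peak.
* **Enrichment** — Fisher's exact test (two-sided, point-probability
  method) with Benjamini–Hochberg FDR, for comparing category retention
  between paleologs and other genes.
* **Synthetic data** — a generator that plants a known duplication history
  (shared WGD, exponential SSD background, TE-flagged families, multicopy
  families) and emits a truth table, so every stage is tested against
  ground truth.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

The numbered scripts under `analysis/` run a complete study on synthetic
data (outputs land in `results/`):

```sh
python analysis/01_simulate.py           # 5 species, WGD planted at 75 Mya
python analysis/02_gene_families.py
python analysis/03_ks_age_distribution.py
python analysis/04_date_wgd.py
python analysis/05_enrichment.py
```

Step 01 simulates 500 ancestral genes down a five-species tree (crown age
56.43 Mya) with a shared WGD at 75 Mya (retention 0.25) and lineage rate
μ = 2.5e-9 /site/yr. The downstream steps then print, among other things:

```
500 families (0 singletons), 268 single-copy orthogroups over 5 species
planted multi-gene families recovered exactly: True

Rap: 174 node-averaged Ks values (provenance {'te_removed': 13,
  'zero_removed': 3, 'saturated_removed': 0, 'clustered_collapsed': 41, ...})
mixture: k=2, BIC=244.3
  component: weight 0.261, peak Ks 0.072     # SSD background
  component: weight 0.739, peak Ks 0.359     # the WGD burst

calibration: Ks 0.2740 at 56.43 Mya -> mu = 2.427e-09 /site/yr (true 2.5e-9)
WGD date for Rap: peak Ks 0.359 -> 73.91 Mya (71.58-76.24); planted truth 75 Mya
```

Reading this: clustering recovered the planted families exactly; the
mixture model separated the exponential SSD background (peak Ks 0.07) from
the WGD burst, locating the peak at Ks 0.359 against a planted 0.375
(2 × 75 Myr × 2.5e-9); the ortholog divergence between the terrestrial and
mangrove-side species calibrated μ within 3% of truth; and inverting
Ks = 2 T μ dated the WGD to 73.9 Mya, within 1.5% of the planted 75 Mya.
The interval is the delta-method propagation of the peak's standard error.

The same stages are available as a CLI (`paleoks simulate | families | ks |
agedist | mixfit | sizer | date | enrich | pipeline`) driven by a single
config file with one global seed; every pipeline run writes a manifest of
input/output checksums and row counts.

As a pure-arithmetic sanity check of the clock: an ortholog divergence of
Ks = 0.28 at a 56.43-Mya calibrated split gives μ = 2.48e-9 /site/yr, and a
WGD peak at Ks = 0.37 under that rate dates to ≈ 74.6 Mya.

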