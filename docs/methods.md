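# Methods

## The discovery model

The pipeline operationalizes a simple generative picture: active
enhancers carry H3K27ac and transcribe short unstable RNAs; gene bodies
transcribe much more; readthrough past a gene's 3′ end can spill
enhancer-like signal into flanking intergenic space.  Each filter
targets one of these confounders:

- **Intergenic selection.**  A peak overlapping any annotated gene body
  (TSS to TES, introns included) is discarded.  The default scope is
  *all* biotypes, not just protein-coding — calling transcription from
  a noncoding gene an "eRNA" would be a category error.  A
  `protein_coding_only` scope is available for annotations whose
  noncoding models are unreliable.
- **±flank windows (default 3000 bp)** around the peak center, where
  the center is the summit when supplied and `floor((start+end)/2)`
  otherwise.  Windows at chromosome edges are clipped, not dropped; the
  `clipped` flag keeps RPKM length-correct.
- **Merging** uses strict half-open overlap (abutting windows stay
  separate); the merged window carries the union of source peaks.
  Merging precedes quantification by default, so the RPKM denominator
  is the merged length; a `merge_before_filter = false` config flag
  reverses the order for sensitivity analysis (on well-spaced data the
  two orders agree, as the test suite asserts).
- **Expression filter**: mean RPKM across all samples strictly > 1.
  "Mean over all samples" is one of three defensible readings
  (`mean`/`any`/`all` are all implemented); the mean is the default
  because with n = 2 per condition a per-sample rule is dominated by
  single-library noise.
- **Readthrough filter**: any window overlapping a protein-coding gene
  body by ≥ 1 base is removed.  Only protein-coding genes trigger
  removal — the confounder being modeled is mRNA readthrough.  No
  minimum-overlap fraction is applied.

Coordinates are 0-based half-open everywhere internally; GTF input is
converted on read.  Chromosome names match by exact string equality.

## The differential engine

NB2 model per feature: counts `y_ij ~ NB(μ_ij, α_i)` with
`var = μ + αμ²` and `log μ_ij = log s_j + β₀ + β₁ x_j`
(`x_j` = 1 for treated samples).

- **Size factors** `s_j`: median over features with all-positive counts
  of `count_ij / geometric mean_i` (the median taken on the ratio
  scale).
- **Dispersion**: the method-of-moments estimate
  `α̂ = max(α_min, (pooled within-group variance − mean)/mean²)` on
  size-factor-normalized counts, with `α_min = 1e-8`.  Raw per-feature
  moment estimates at 2–3 replicates are far too noisy to plug into a
  Wald test (features whose variance is underestimated get floored
  dispersions and grossly anticonservative p-values), so the default
  squeezes them toward the common mean with weight `df/(df + prior_df)`
  (`prior_df = 20`, `df` = pooled residual degrees of freedom).  This
  is the package's chosen compromise between per-feature flexibility
  and calibration; the raw estimator remains available as
  `method="per_feature"`.  No trend fitting or empirical-Bayes
  posterior is attempted.
- **Fitting**: IRLS with working weights `μ/(1+αμ)`, iteration cap 25,
  convergence at relative deviance change < 1e-8, linear predictor
  clamped to ±30 so separated fits (a group with zero counts) terminate
  deterministically.  The Wald statistic is `β₁/se(β₁)` with the
  standard error from the observed information; two-sided normal p.
- **Reporting**: `log2FC = β₁/ln 2`.  When one group's counts are all
  zero, the *reported* log2FC uses a 0.5 pseudocount on normalized
  group means to avoid ±∞; the test statistic never does.  All-zero
  features get p = 1, log2FC = 0, and an `all_zero` flag.
- **FDR**: Benjamini–Hochberg step-up with monotonicity enforcement.
- **Calls**: strict inequalities — `up` iff FDR < 0.05 and
  log2FC > 1; `down` symmetric.  The fold-change cut is applied
  two-sidedly since both directions are reported under the same rule;
  gene-level analyses can set `lfc_cut = 0`.

## Motif model

IR1 geometry is hard-wired: half-site, 1-bp spacer, reverse-complement
half-site (13 bp total).  The default half-site consensus is RGGTCA —
the canonical nuclear-receptor hexamer — with IUPAC-aware matching and
a per-half mismatch budget (default 1).  A 6×4 PWM with uniform 0.25
background and 0.01 pseudocount can be attached for log-odds scoring;
no PWM is shipped because none is pinned by the data the package
models.  A perfect IR1 is its own reverse complement, so scanning one
strand covers both; hits are reported once per position.

## Validation statistics

- **Metaprofile**: mean binned coverage over ±flank around region
  centers; regions too close to an edge are skipped with a warning.
- **Permutation enrichment**: observed mean signal over target regions
  vs the null of `n_perm` draws of equally many regions from a control
  pool without replacement; `p = (1 + #{null ≥ obs})/(1 + n_perm)`.
  The recommended pool is the silent intergenic windows the caller
  itself produces — length-matched by construction, which removes the
  main covariate without external data.
- **GRO-seq dependence**: with n = 2 per genotype × condition group a
  per-feature test is indefensible, so dependence is summarized at the
  set level: per-eRNA `lfc_g = log2((mean_{g,treated}+ε)/(mean_{g,vehicle}+ε))`
  on normalized counts (ε = 1 normalized count bounds sparse-window
  fold changes), and `Δ = median(lfc_flox) − median(lfc_lko)`.  An
  optional sign-swap permutation (exchanging each eRNA's flox and lko
  fold changes) gives a one-sided set-level p for Δ > 0.

## Synthetic data

The generator emulates the *statistical* structure of the real study,
not its sequences: a 3 Mb chromosome; 30 protein-coding and 5 noncoding
genes; 8 induced (log2FC +3), 2 repressed (−3), 10 constant and 30
silent intergenic enhancers; 20 genic peaks; 5 readthrough decoys
(intergenic peaks whose ±3 kb window reaches a protein-coding gene
body).  Counts are NB with mean 500 (vehicle) for expressed enhancers,
dispersion α = 0.05, and 2 libraries per condition — matching a design
of two pooled libraries per condition; the true |log2FC| of 3 mirrors
the ~10-fold induction scale typical of strong agonist responses.
Silent regions draw from mean 1, which sits well below 1 RPKM at the
800k–1.2M library sizes used.  RNA-seq is materialized as read
5′-position files: planted reads uniform within each truth window plus
background reads placed inside gene bodies so the library total is
exact and intergenic windows see only planted signal.  GRO-seq is a
count matrix over the four genotype × condition groups with the fold
change applied only in receptor-intact treated samples.  Sequences are
uniform random with one perfect IR1 planted at the center of every
induced region.

Regions are laid out left-to-right with gaps ≥ 2×flank, so truth labels
are unambiguous under merging and every truth region maps 1:1 onto one
pipeline window.  All randomness flows through named SHA-256-derived
substreams of a single seed, making every artifact byte-identical
across reruns.

**What passing tests do not show**: the generator has no alignment
artifacts, no multimapping, no batch effects, no dispersion-mean trend,
no correlated neighboring windows, and uniform (not peak-shaped) read
placement.  Truth recovery on it demonstrates the pipeline's logic and
the engine's calibration, not performance on real libraries.

## Problem sizes and numerical choices

Test and acceptance workloads are desk-scale by design: the default
fixture runs end to end in a few seconds; null calibration uses 2,000
NB features at n = 3 vs 3 (plus 20 × 500-feature replicates for the BH
check); oracle comparisons use randomized inputs up to 100 kb.  The
permutation p-value lower bound is 1/(n_perm + 1).  Ties in BH are
handled by the monotone step-up; ties in interval sorting by
(chrom, start, end).  Degenerate inputs (empty peak lists, all-zero
features, empty gene annotation) return empty results or flagged rows
rather than raising, except where a result would be statistically
undefined (no all-positive feature for size factors; dispersion without
replicates), which raise with instructive messages.

## Known limitations

- Two-group designs only; no covariates, interactions, or
  likelihood-ratio tests.
- No dispersion trend or posterior shrinkage; very small dispersions on
  real data may remain slightly anticonservative.
- Strand-aware counting supports 5′-position input only (no fragment
  or paired-end model).
- The enrichment test matches control regions by length only, not GC
  or mappability.
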