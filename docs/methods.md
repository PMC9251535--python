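# Methods

## Overview

`regwas` aggregates GWAS summary statistics over *regulatory elements*
(REs) — promoters and enhancers active in a disease-relevant tissue —
instead of gene bodies. The motivation is that most common risk
variants are noncoding and act through regulatory elements that may sit
far from their target gene, so a gene-body scan misassigns or misses
them. The pipeline has five stages:

1. **Tissue filtering.** An RE catalog (with many-to-many RE-to-gene
   links) is restricted to elements that overlap a tissue H3K27ac peak
   set by at least one base pair. Peaks are merged (union of
   overlapping or bookended intervals) before filtering. Retained
   elements are classified as *promoters* (overlapping a window of
   1,000 bp upstream to 100 bp downstream of any gene's TSS,
   strand-aware) or *candidate enhancers* (everything else).
2. **Feature-level association.** SNPs are positionally assigned to
   every (optionally window-extended) element containing them. Per
   element, two-sided SNP P-values are inverted to 1-df chi-squares
   and averaged; the null of the mean statistic accounts for LD through
   the eigenvalues of the SNP correlation matrix estimated from a
   reference panel (below).
3. **Gene collapse.** Each gene linked to at least one tested element
   receives the minimum P over its elements (the "best" element
   represents the gene); a Sidak min-P adjustment for the number of
   tested elements is reported alongside but not substituted for the
   primary P-value (see Design choices). Genome-wide significance uses
   a Bonferroni threshold alpha / n_genes with strict inequality.
4. **Ranking and enrichment.** Genes are ranked by -log10(P)
   descending; ties are broken by -log10(P) x mean tissue expression,
   then gene id, after removing an optional exclusion list (e.g. the
   HLA region, whose long-range LD otherwise clusters many gene-level
   hits and can fabricate pathway enrichments). Preranked GSEA runs on
   this list against GMT gene sets and against a super-enhancer TF set
   constructed from a TF list, a super-enhancer BED and gene locations.
5. **Nexus TFs.** A transcription factor is called a *nexus* TF when it
   is (a) on the leading edge of the super-enhancer TF enrichment and
   (b) its best (minimum-P) target-gene set is itself enriched with
   nominal P < 0.05 and FDR q < 0.25 (strict cuts).

## The feature statistic and its null

For an element with m SNPs, let z_j^2 be the 1-df chi-square obtained
by inverting SNP j's two-sided P-value, and let R be the m x m Pearson
correlation matrix of reference-panel dosages with eigenvalues
lambda_1 >= ... >= lambda_m >= 0. The statistic is

    T = (1/m) * sum_j z_j^2,     m*T | H0  ~  sum_i lambda_i chi2_1(i).

Under the null, z ~ N(0, R) asymptotically, so the quadratic form z'z
is a weighted sum of independent 1-df chi-squares with the eigenvalues
of R as weights. Duplicated or strongly correlated SNPs concentrate
mass in fewer eigenvalues, so an element dense in redundant SNPs is not
rewarded; an element of m independent SNPs reduces exactly to
chi2_m / m.

The survival function of the weighted sum is evaluated by numerical
inversion of the characteristic function (Imhof's formula). The
integrand oscillates at frequency q/2 (q the quantile) with a slowly
decaying envelope, which defeats plain adaptive quadrature on a long
range; we therefore integrate the head [0, 1] adaptively and the tail
with Fourier-weight (QAWF) quadrature after expanding
sin(phi - qu/2) into sin/cos components. Absolute tolerance is 1e-10;
verified against closed forms (equal eigenvalues = scaled chi-square)
to ~1e-13 and against 10^6-draw Monte Carlo within sampling error.
When the integral is unreliable (estimated error > 1e-7, value outside
[1e-9, 1]) the evaluator falls back to the two-moment
(Satterthwaite-Welch) scaled chi-square, which is exact for equal
eigenvalues and accurate in deep tails where the analytic integral
loses relative precision; the method used is recorded per call.
Numerically, P-values around the switch point (~1e-9) may move by less
than the integration tolerance; monotonicity of P in any z_j^2 holds
exactly within either regime.

Eigenvalues below 1e-5 x lambda_max are not counted as model
parameters (`n_params`), mirroring the principal-component pruning of
regression-based gene analysis; they contribute nothing numerically to
the null either. The GWAS sample-size column is read and carried
through but does not enter the statistic — only P-values and LD do.

A raw-data mode (`pc_regression_ftest`) is included for
individual-level genotypes: genotypes are projected onto principal
components explaining 99.9% of variance (rank-deficient directions
dropped) and the phenotype regressed on them with a joint F-test.

## Preranked GSEA

The running-sum statistic walks the ranked list; hits advance by
|score|^w / N_R (w = 1 by default; w = 0 gives the unweighted KS form)
and misses retreat by 1/(N - n). ES is the maximum deviation from
zero. The null is built from `nperm` random same-size gene sets (set
permutation — the only scheme available for preranked input), seeded
per set via `SeedSequence` children so results are independent of
evaluation order. NES divides ES by the mean magnitude of same-sign
null scores; nominal P is the same-sign null exceedance fraction,
floored at 1/nperm (reported as a bound rather than 0); FDR q follows
the standard two-tail NES procedure with pooled normalized null
scores and isotonic (cumulative-minimum) monotonicity enforcement.
Sets intersecting the list in fewer than `min_size` (default 3) or
more than `max_size` (default 800) genes are skipped with a reason;
pathway-style analyses should additionally raise the minimum to 25,
where NES size-normalization becomes stable.

## Synthetic data

The generator emulates every input: a dosage reference panel, GWAS
summary statistics, an RE catalog with many-to-many links, peak /
super-enhancer BEDs, gene locations, an expression table and GMT sets.

* **Genotypes**: latent Gaussians with block-AR(1) correlation,
  thresholded at Hardy-Weinberg cutpoints for a per-block MAF drawn
  from `maf_range` (default (0.1, 0.5)). The latent correlation is
  calibrated (inverse of the tetrachoric-style attenuation, solved by
  root finding on the analytic dosage correlation) so the *realized*
  adjacent-dosage correlation matches `within_block_rho` (default
  0.8). One LD block per regulatory element, plus one per gene body
  so a conventional gene-body scan sees SNPs too; blocks are mutually
  independent. Default panel size 5,000 samples — large enough that
  realized LD tracks its target within sampling error.
* **Summary statistics**: per block, z ~ N(R delta, R) with R the
  realized dosage correlation; a causal element's noncentrality ncp is
  spread over its m SNPs as delta_j = ncp / sqrt(m), so LD neighbours
  inherit r-scaled shifts exactly as in real summary data. Two-sided
  P-values from z.
* **Landscape**: genes on one chromosome at 60-kb spacing with
  alternating strands; each gene owns one primary RE (40% inside the
  promoter window, 60% distal intergenic), extra REs occupy intergenic
  slots and link up to `links_per_re` random genes. All elements are
  >= 3 kb apart, so the configured unsupported fraction (default 0.2)
  is removed *exactly* by the peak filter. Expression is log-normal;
  TFT-style gene sets have 25-40 members; ten TFs carry
  super-enhancers over their gene bodies.

Default study conditions: 200 genes, 300 REs, 10 SNPs per block,
rho = 0.8, 5,000 panel samples. What the generator does **not**
emulate: realistic allele-frequency spectra, recombination-driven LD
decay, cross-block LD, population structure, imputation noise, or
signed effect directions shared across SNPs. Passing tests therefore
demonstrate the statistical machinery (calibration, LD handling,
ranking, enrichment logic) — not robustness to those real-data
complications.

All randomness flows from the single config seed through named
`numpy.random.SeedSequence` children (`landscape`, `panel`, `gwas`),
so any seeded artifact is byte-reproducible.

## Design choices

* **Coordinates**: 0-based half-open everywhere internally; BED read
  as-is; GFF-style catalogs and gene locations (1-based inclusive)
  converted on read. Overlap means half-open intersection length >= 1,
  which makes "at least one base pair" unambiguous on touching
  intervals.
* **Chromosome labels** are normalized (leading `chr` stripped,
  X/Y/MT uppercased) so UCSC- and NCBI-style inputs mix.
* **SNP matching is by rsID**, not position, when joining summary
  statistics to the panel; multi-allelic and strand-ambiguous variants
  are not specially handled.
* **P = 0 inputs** are clamped to the smallest positive double with a
  warning rather than rejected — summary files commonly underflow.
* **Min-P gene collapse without multiplicity substitution.** The Sidak
  adjustment 1 - (1 - p)^k (computed stably via expm1/log1p) is
  reported per gene, but the primary gene P stays the raw minimum:
  the feature test already accounts for SNP count per element, the
  adjusted and unadjusted rankings correlate almost perfectly among
  top genes, and substituting the adjustment trades type-I for
  type-II error. A diagnostic (`diagnostics.spearman`) quantifies the
  pre/post-adjustment rank agreement.
* **Distance convention**: enhancer-TSS distance uses the element's
  start coordinate, not its midpoint.
* **Promoter windows** are evaluated against every gene's TSS (one TSS
  per gene row), not only the element's linked genes.
* **"Proximal" for SE-TF membership** is a 50-kb TSS window by
  default (configurable); per-TF provenance (overlap / nearest /
  proximal) is recorded because the three rules overlap.
* **Bootstrap comparison** resamples both P-value lists independently
  (10,000 replicates) and reports the smoothed fraction of resampled
  mean -log10(P) differences <= 0; the statistic and sidedness are a
  package convention, documented rather than inherited.
* **LD bins** are consumed as a BED; a greedy fallback builder cuts a
  new bin when a SNP's max r-squared with the previous (up to 200)
  SNPs of the current bin drops below 0.1.
* **Negative-control TFs** ("bottom 16") can be ordered by largest
  nominal P or smallest NES; both orderings are exposed since the
  convention is ambiguous.

## Degenerate inputs and tie-breaks

Ties in the best element per gene go to the smaller RE id; ties in
nearest-TSS go to the lexicographically smaller gene id; residual ties
in the ranked list go to gene id ascending — every ordering in the
pipeline is total, so outputs are byte-stable. An element whose SNPs
are all monomorphic in the panel is skipped with a reason code; a gene
set covering the entire ranked list has no misses and is skipped; an
empty peak set is a fatal error (it would silently null the analysis).

## Problem sizes used in the checks

The acceptance checks run at desk scale: 2,000 simulated features for
null calibration; 20 spectra x 5 thresholds against 10^6-draw Monte
Carlo; 100 random instances for the interval oracles; 500 replicates
for GSEA null uniformity; and 50 simulated studies (200 genes, 300
REs, 5,000-sample panel, one causal element at noncentrality 6) for
end-to-end recovery. These sizes give the statistical properties room
to fail visibly while keeping a full run to a few minutes.

## Known limitations

* The summary-statistic model is the mean-of-chi-squares ("mean z²")
  formulation; top-SNP and hybrid models, conditional/joint analysis
  and gene-property regression are out of scope.
* Set permutation is the only GSEA null; score permutation schemes are
  not implemented.
* The min-P collapse simplifies multi-element regulation: additive or
  hierarchical contributions of several elements to one gene are
  not modelled.
* The panel is consumed as a plain dosage matrix; VCF parsing,
  phasing and imputation are out of scope.
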