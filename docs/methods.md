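# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Coordinates and formats

All coordinates are 0-based half-open, in memory and on disk (BED /
bedGraph convention). Gene annotation is a minimal TSV (`chrom start end
strand gene_id`) because the analysis needs only TSS, TES and strand. On
the minus strand the TSS is `end − 1`, the TES is `start`, and "upstream"
moves toward larger coordinates. Coverage tracks are fixed-width bins
(default 100 bp — fine enough to resolve promoter-scale features while
keeping a 2-vs-2 variance estimable); the last bin of a chromosome is
truncated, never dropped. bedGraph records are resampled onto the bin
grid by coverage-weighted means, which preserves total signal mass up to
grid truncation.

## Differential counts (RNA-seq and PRO-seq)

Counts for gene *g*, sample *s* are modeled as negative binomial with
mean `f_s · μ_g` and variance `μ + α μ²` (`f_s` the sample's size
factor, `α` the dispersion). PRO-seq matrices run through the identical
machinery; separating pause-site from gene-body signal is out of scope.

* **Normalization** — median-of-ratios: `f_s = median_g (c_gs /
  geomean(c_g))` over genes positive in every sample. Rescaling counts by
  the estimated factors is a fixed point (re-estimated factors ≈ 1).
* **Dispersion** — per-gene method of moments on normalized counts,
  `α_g = max((var_g − mean_g)/mean_g², 10⁻⁸)`, with the variance pooled
  within the WT and MUT groups. With two samples per group this estimate
  has two degrees of freedom and is far too noisy to plug into a Wald
  test directly (the normal reference becomes badly anticonservative),
  so the test uses a **moderated dispersion**: the mean of the per-gene
  estimates over all genes in the same base-mean decile. Decile pooling
  lets dispersion depend on expression level without fitting a
  mean–dispersion trend. Measured type-I error at nominal 0.05 under a
  2-vs-2 NB null is ≈ 0.05 (the test suite asserts the [0.02, 0.08]
  band); the raw per-gene estimate gives ≈ 0.15.
* **Wald test** — `log2FC = log2((μ̂_MUT + pc)/(μ̂_WT + pc))` with
  pseudocount `pc = 0.5` on normalized group means for stability at
  zeros; the standard error comes from the delta method on the NB
  variance of each group mean (`Var(mean) = Σ_s (μ/f_s + αμ²)/n²`);
  two-sided p from the standard normal; BH adjustment across genes.
* **Calls** — `up` if `q < α` (default 0.05) and `log2FC ≥ 1`; `down`
  symmetric; otherwise `ns`. Thresholds are configurable; the defaults
  are conventional, not derived.

## Occupancy mapping (FLAG vs H2A internal control)

Each sample is reduced to a per-bin ratio
`r = log2((flag_c/F + ε)/(h2a_c/H + ε))` with `F`, `H` the sample's FLAG
and H2A library totals computed from the tracks themselves, and
`ε = pc / n_bins` a pseudocount expressed **in units of the sample's
mean bin count** (default `pc = 1`, i.e. one average-coverage count).
Writing the pseudocount on the depth-normalized scale makes `r` exactly
invariant to rescaling a sample's tracks by any constant — a fixed raw
count offset would not survive a depth change.

Per bin, `Δr = mean_MUT(r) − mean_WT(r)` is tested with a z statistic
whose pooled within-group variance is moderated by averaging over all
bins in the same coverage decile (coverage = mean depth-normalized
FLAG+H2A signal): with two clones per group a per-bin variance is
hopeless, but thousands of bins at similar coverage share an error
scale. BH across bins; bins with `q < α` are merged into peaks when
separated by at most `max_gap = 1` non-significant bin, runs of fewer
than `min_bins = 2` bins are dropped. Per-peak `Δr` is the
width-weighted mean, per-peak p the Fisher combination of member-bin p,
and peak q-values are BH across peaks. Mutant-specific peaks are those
with `Δr > 0` and `q < α` — only mutant-elevated occupancy counts.

## Peak annotation and the shuffled null

Peaks are assigned exactly one category with precedence
promoter > gene body > intergenic on any ≥ 1 bp overlap (promoter =
strand-aware TSS ± 1 kb by default; the window is configurable because
no universal definition exists). The null for the category distribution
re-places every peak uniformly on its own chromosome with its own
length (so the length multiset and per-chromosome composition are
conserved); shuffled peaks may overlap one another (pure uniform null; a
rejection-sampling non-overlapping mode exists behind a flag). Expected
counts are the mean over shuffles (default 1000) rescaled to the
observed total, and `χ² = Σ(O−E)²/E` is referred to the χ² distribution
with k − 1 degrees of freedom. ATAC co-localization counts ≥ 1 bp
overlaps via a sorted-sweep over merged ATAC intervals (tests verify the
sweep against an all-pairs scan).

## Locus-wide enrichment and GSEA

A gene's locus window runs from 1 kb upstream of its TSS to its TES,
strand-aware, clipped at chromosome boundaries (and flagged when
clipped). Its score is the width-weighted mean of per-bin `Δr` over the
window. Genes are ranked by descending score with lexicographic gene-id
tie-breaks (deterministic by construction).

The GSEA running sum walks the ranking: a hit increments by
`|score|^w / Σ_hits |score|^w`, a miss decrements by `1/(N − N_hit)`;
the enrichment score is the signed extremum by absolute value, taken at
the earliest rank within 10⁻⁹ of the maximum so that float-level ties
cannot flip the sign. Weight `w = 1` (classic weighted GSEA) is the
default; `w = 0` gives the analytically clean unweighted walk (the sum
ends at exactly 0 and `|ES| ≤ 1`).

The permutation null draws random gene sets of the same size from the
ranked universe, `p = (1 + #{|ES_null| ≥ |ES_obs|})/(n_perm + 1)`
(add-one estimator, so p ≥ 1/(n_perm+1) and never 0), default
`n_perm = 10000`. Set-membership permutation was chosen over
sample-label permutation deliberately: with two clones per genotype only
six label splits exist, which cannot support a 10⁻⁴-resolution p-value.

Per-gene locus-wide enrichment calls use per-sample locus-mean `r`
values compared between genotypes with the same decile-moderation device
as the bin test, stratified by window length (longer windows average
more bins and are intrinsically less noisy); BH-adjusted `q < α` with a
positive difference is called enriched.

## Concordance

The shared universe is the intersection of genes tested in both assays
(dropped genes are reported). Quadrant buckets — up in both, down in
both, one-sided in either assay, discordant, neither — partition the
universe; opposite-direction genes get their own `discordant` bucket
rather than being folded into one-sided counts. Pearson r of the fold
changes uses the t reference with n − 2 df. Over-representation of
user-supplied gene sets is an upper-tail hypergeometric test with BH
across sets; no pathway database is bundled (versioned databases would
break reproducibility).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the pipeline targets: 2
wild-type + 2 mutant clones; RNA-seq in duplicate per clone (8 columns)
and PRO-seq once per clone (4 columns); FLAG and H2A binned coverage per
clone; ATAC peaks at every promoter (so the co-localization denominator
is never degenerate) plus 200 random background peaks.

* Genes: 2000 non-overlapping genes of 1–5 kb placed uniformly on
  2 × 10 Mb chromosomes (≈ 30% gene density — enough genes for stable
  calibration while keeping runtimes in seconds).
* Counts: gamma–Poisson (exact NB) with a single shared dispersion 0.05
  (a mid-range bulk RNA-seq value) and per-gene baselines log-uniform on
  [20, 500]. A single dispersion, not a mean–dispersion trend, keeps the
  planted-recovery properties analyzable. Clone-to-clone biological
  variability is a per-clone log-normal factor (σ = 0.1); per-sample
  depth factors exist but default to 1.
* Planted truth: 5% of genes up, 5% down at ±2 log2 units in the mutant
  clones; 40% of the up-genes additionally get locus-wide FLAG
  enrichment of 3 log2 units over their full locus window in mutant
  clones only (H2A stays flat — the control is genotype-independent).
  FLAG targets are drawn only from up-genes whose locus windows overlap
  no other gene's window: planting enrichment at a non-isolated gene
  would spill signal into a neighbor's window, and the neighbor — which
  the detector would correctly flag — would have no truth label. Tracks
  are Poisson around 20 counts/bin at 100 bp bins.
* Emitted pre-binned, not as reads: the pipeline's unit of computation
  is the bin. Consequently read-level artifacts — fragment-length
  effects, GC bias, alignment multimapping, spike-ins — are not
  modeled, and passing tests say nothing about robustness to them.
  Likewise the NB-with-shared-dispersion count model cannot reveal
  sensitivity to dispersion outliers, and the planted effects are
  uniform over the locus window, which is kinder than real, ragged
  enrichment profiles.

Every generator output is a pure function of (config, seed); independent
deterministic substreams per stage are derived by hashing the seed with
a stage tag.

## Numerical conventions and degenerate inputs

* p-values are clipped to [0, 1]; Fisher combination clips member p at
  10⁻³⁰⁰ before logs; BH is the statsmodels step-up implementation.
* Zero-mean genes get the dispersion floor (10⁻⁸) and a flag; zero-total
  tracks are an error; empty peak sets skip the annotation stage.
* Ratio-track grids must match exactly; a mismatch is an error, never a
  silent resample.
* Running-sum extremum ties (within 10⁻⁹) resolve to the earliest rank.
* Gene ranking ties resolve lexicographically by gene id.
* The pipeline re-runs bit-identically for fixed (inputs, config, seed);
  stage subcommands recompute from the raw inputs deterministically, so
  stage output ≡ the corresponding slice of a full run.

## Problem sizes

Default analysis scale — 2000 genes, 20 Mb genome, 200k bins of 100 bp,
8 count columns + 4 coverage-track pairs, 1000 shuffles, 10000 GSEA
permutations — was chosen so a full end-to-end run completes in seconds
on one core while leaving every statistic comfortably powered (planted
recovery at sensitivity/precision ≥ 0.9 and calibration bands of a few
percent are measurable at n = 2000).

## Known limitations

* The Wald test with decile-moderated dispersion is calibrated under the
  generator's NB model; heavy-tailed real count data (dispersion
  outliers) would need per-gene shrinkage methods that are deliberately
  out of scope here.
* The occupancy z-test assumes bins at similar coverage share a variance
  scale; strong sample-specific artifacts (e.g. one clone with locally
  corrupted signal) violate the pooling.
* Locus-wide scores weight all bins equally; a promoter-proximal-only
  signal dilutes toward 0 over a long gene — by design (the statistic
  targets locus-wide enrichment), but worth remembering when comparing
  genes of very different lengths.
* The χ² test treats the shuffle-mean expectation as known; with very
  few shuffles the extra Monte-Carlo variance makes it anticonservative
  (the default 1000 shuffles makes this negligible).
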