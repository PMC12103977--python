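# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical conventions a maintainer would need.

## Study design being emulated

Four passerine taxa on a known rooted tree (branch lengths in Myr, depth
8.7): two native snowfinch sister taxa (split 5.7 Myr ago), and a tree
sparrow species whose high-elevation population colonized the plateau very
recently (split from the low-elevation population ~0.0026 Myr ago). Sample
sizes follow the study design: 9/8/9/7 individuals (low-elevation reference,
colonizer, RN-snowfinch, WR-snowfinch) for phenotypes, with 6 low-elevation
RNA samples (30 expression samples total, hence 29 usable PC axes in
expression space). Polymorphism uses n = 22 chromosomes (11 diploids) per
high-elevation taxon.

## Phenotypes and morphospace

Five traits with study-like units and baselines: heart mass/body mass ratio
(1.34 ± 0.08), cardiomyocyte cross-sectional area (52.64 ± 6 µm²), capillary
density (3,864 ± 250 /mm²), and the two residual traits (cardiomyocyte size
against heart mass; capillary density against cardiomyocyte size). Taxon
shifts reproduce the study's group contrasts (colonizer: hypertrophy-like
increases; natives: large capillary-density increases). Taxon means add a
Brownian deviation (per-trait rate defaulting to (0.3·SD)²/tree-depth — a
modest phylogenetic signal relative to the planted shifts); individuals add
multivariate normal noise with a 0.3 within-taxon correlation (the
P-matrix). A non-positive-definite P-matrix is rejected.

Phylogenetic PCA standardizes traits (z-score across individuals) by
default because the traits mix units spanning four orders of magnitude; the
covariance-based variant is `scale=False`. The PCA operates on taxon means
under the Brownian covariance; individuals are projected onto mean-derived
axes because morphospace clouds are individual-level. With t taxa, R has
rank t − 1; axes beyond that are an orthonormal completion with ~zero
eigenvalues (tests compare only identifiable axes). Sign convention: each
axis's largest-|loading| element is positive.

**TSV convention.** The divergence statistic is defined here as the per-axis
reference-standardized Euclidean distance averaged over 5,000 Monte-Carlo
draws (independent normals per axis, since PC axes are uncorrelated by
construction). The reference's own per-axis SD standardizes by default; a
pooled-SD variant is available (`pooled_sd=`). Absolute agreement with any
particular published TSV value is not claimed — the statistic is
scale-consistent, not anchored: note that a distribution-matched taxon has
expected TSV ≈ E‖z‖ ≈ √K, not 0. HSD contrasts treat each draw as one
observation; draws are pseudo-replicates, so the HSD p-values index
separation of simulated distributions, not raw-data significance.

## Cross-species normalization

Reciprocal best hits use e-value strictly < 1e-10 AND identity ≥ 30%; best
hit per query by bitscore, ties broken by lower e-value then lexicographic
subject id; three species are joined by intersecting pairwise maps through
the tree-sparrow pivot (the common comparator). The conserved-gene CV uses
the population SD (ddof = 0) on raw TPM; a log-scale option exists. The
"common value" is the reference-species median: factors are the gene-wise
median of (reference median / species median) over conserved genes
(median-of-ratios; a pooled-median variant is a flag) — robust to a handful
of divergent conserved genes. Genes with a zero median in any species are
dropped from factor estimation with a warning.

The generator plants species scale offsets of 1/1.298 and 1/1.374 on the two
snowfinch genomes and a block of ≥ moderately many low-noise conserved genes
(log-normal noise, SD 0.05) so the scaling stage is well-posed; recovered
factors are then 1.298/1.374 against the tree sparrow. TPM columns are not
re-normalized to 10⁶ after scaling (that would erase the planted offsets the
stage exists to estimate).

## Co-expression

Log1p-TPM of the normalized matrix feeds an unsigned network |cor|^β. The
soft threshold is the smallest β ∈ 1..20 whose log-log degree-distribution
fit reaches R² 0.8, else the argmax with a warning (planted-module data is
not globally scale-free, so the warning path is common and harmless —
module recovery is insensitive to β in the 10–20 range here). TOM uses the
standard shared-neighbor formula; clustering is average linkage on TOM
dissimilarity with a **static branch cut** (height 0.99, min size 30) in
place of hybrid dynamic tree cut: deterministic, dependency-free, and
sufficient for planted-structure recovery; the cut height is exposed in
config. Eigengenes are unit-norm PC1 of the module's gene-standardized
expression, sign-flipped so the mean gene–eigengene correlation is positive.

Module–trait association is a random-species-intercept model fit by ML with
a χ²₁ likelihood-ratio p against the trait-free model and Nakagawa marginal
R² = var(fixed)/(var(fixed) + var(intercept) + var(residual)); fewer than 3
species or 6 samples falls back to OLS with a warning. "Significant" is
marginal R² > 0.3 and p < 0.05. GS is the absolute gene–trait correlation,
maximized over the module's significant traits (falling back to all traits
when none is significant); a signed variant is a flag. Because the taxa
differ strongly in trait means, much of a trait's variance is between
species and is absorbed by the random intercept — marginal R² is therefore
systematically below the naive squared correlation, and recovery tests
compare against the truth-implied mixed-model R² rather than the generating
coupling a².

The expression generator plants three modules (default 100 genes each)
whose latent factors follow the study's module–trait pairs (capillary
density, heart-mass ratio, cardiomyocyte-size residuals) with coupling
a = 0.85, gene loadings in 0.5–1.0, and log-scale member noise SD 0.2 —
chosen so within-module gene correlations sit near 0.8, the regime of
strong co-expression modules. Genes with loading ≥ 0.8 are recorded as
planted hubs.

## Sweep scan

Everything is folded (no outgroup is simulated or required). The background
spectrum pools all sites genome-wide with a 0.5 pseudocount per class. The
escape model follows the star-phylogeny approximation described in the
README; the per-window likelihood conditions on polymorphism (the mixed
class distribution is renormalized over classes 1..⌊n/2⌋). The α grid is 12
log-spaced points per decade over [1e-5, 1e-1] per bp plus the exact
neutral point (p_e = 1), which guarantees CLR ≥ 0; site distances are
clipped at 1 bp. The sweep center sits at the window midpoint — one
evaluation per window. Only rank order matters for outlier selection, so
the 2·ln convention is cosmetic. Windows with S = 0 are flagged and
excluded from ranking; top-1% selection takes the ⌈0.01·N⌉-th best score as
threshold and keeps all ties.

π uses the unbiased per-site estimator 2j(n−j)/(n(n−1)) summed over sites;
Tajima's D uses the standard 1989 constants and is undefined (NaN) at S = 0;
n < 4 is rejected.

The polymorphism generator draws independent sites (no LD): neutral windows
have S ~ Poisson(a₁·θ·L) with folded classes ∝ 1/j + 1/(n−j); θ defaults to
0.003/bp (typical avian genome-wide diversity; mean S ≈ 22 per 2-kb window
at n = 22). Sweep windows reduce S by f_s = 0.2 and mix the class
distribution (weight w = 0.8) with the hitchhiking-escape conditional at
escape probability 0.02 — the physically expected "excess rare" folded
signature (escaped variants stay rare; hitchhiked variants reach high
frequency and fold back into rare classes). Independent sites are adequate
here because the CLR is a composite likelihood over sites.

**Known power limit.** A swept 2-kb window retains only S ≈ 4.4 sites, and
the per-site log-likelihood gain of the conditional CLR is bounded by
ln(1/q₁) ≈ 1.15 nats, while the top-1% neutral threshold over 10,000 windows
is ≈ 6.5–7 (neutral windows with chance singleton excess). Per-window
sensitivity of the top-1% rule for these planted sweeps is therefore ~30–45%
in practice — an intrinsic information limit of per-window folded scans at
this sweep strength, not an implementation artifact. Scans that integrate
sites across many windows around each candidate position do not share this
limit.

## Enrichment permutation tests

Coordinates are 0-based half-open internally; GFF3 is converted on read.
Gene models carry 2-kb strand-oriented flanks, truncated at contig edges
(rather than discarded, keeping all genes testable) and not trimmed when
they overlap a neighbour's body. Window classification is multi-label with
a ≥ 1 bp overlap rule; a window is intergenic only if it overlaps nothing,
and a combined "regulatory" class (upstream or downstream) is reported
alongside the three base classes.

`region_enrichment` resamples |selected| windows uniformly **without**
replacement from all scored windows (with-replacement is a flag), 1,000
times, and calls the empirical proportion at the 95th/99th null percentiles.
`gene_clr_test` summarizes a gene's region by the **max** CLR over
overlapping windows (mean is a flag) and draws class-matched nulls from the
pooled gene-associated windows of all genes, per region class; genes whose
region overlaps no scored window are flagged untestable. Both tests are
seeded and bitwise reproducible.

## Pipeline problem sizes and determinism

The default end-to-end bundle uses 2,000 orthologs (600 conserved,
3×100 module genes), 200 placed genes on a 4-Mb genome (2,000 2-kb
windows), and three taxa of polymorphism with sweeps planted at 1% of
windows, 3-fold over-weighted in hub-gene flank windows — sizes chosen so a
complete run takes seconds to minutes on one CPU while every stage keeps
its statistical character; all counts scale up through configuration. Every
stage derives its RNG stream from the run seed via spawned `SeedSequence`s;
re-running with the same seed reproduces all outputs byte-for-byte
(manifest wall-times aside). At this scale the per-taxon enrichment test
has only ~20 selected windows, so the pipeline demo is calibrated but
under-powered; the focused calibration/power experiments use 100-window
selected sets.

## Limitations

- Independent-site polymorphism: no LD, no recombination maps; π/D/CLR
  sampling covariances across adjacent windows are absent.
- The expression model is log-normal with a single latent factor per
  module; no count-level (negative-binomial) noise, batch structure, or
  isoform effects.
- The morphospace generator plants taxon shifts directly; it does not
  simulate the measurement process behind the residual traits.
- Phylogenetic PCA with four taxa cannot fully separate phylogenetic
  closeness from shared adaptation; TSV contrasts inherit that caveat.
- Passing recovery tests on synthetic data shows the machinery is correct
  under the generator's assumptions; it does not certify performance on
  real data with LD, mapping artifacts, or expression batch effects.
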