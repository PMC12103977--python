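# altadapt

Analyses for studying how bird taxa adapt to high-elevation hypoxia, linking
three layers of evidence in one tested pipeline:

1. **Phenotype divergence** — phylogenetic PCA of cardiovascular traits
   (relative heart mass, cardiomyocyte size, capillary density, and their
   residual traits) and a distance-like divergence statistic, *total
   standardized variation* (TSV), with Monte-Carlo effect sizes and Tukey HSD
   contrasts.
2. **Cross-species transcriptomics** — reciprocal-best-hit ortholog calling,
   conserved-gene scaling factors to put TPM on a common scale across
   species, weighted co-expression networks with module eigengenes,
   mixed-model module–trait association, and hub-gene calling.
3. **Signatures of selection** — a folded-SFS composite likelihood ratio
   (CLR) sweep scan in non-overlapping 2-kb windows with windowed π and
   Tajima's *D*, and permutation tests for enrichment of top-CLR windows in
   hub-gene genic and 2-kb flanking regions.

It is aimed at comparative/population genomicists working with a small clade
— here two snowfinch species native to a high plateau, a recently colonizing
tree sparrow population, and its low-elevation source population — who need
the full phenotype → expression → selection chain reproducible end to end.
A first-class synthetic-data generator emulates the study design with known
ground truth, so every stage is testable without any external download.

## Models in brief

**Phylogenetic PCA.** Traits evolve by Brownian motion on a rooted tree with
branch lengths; the expected covariance of taxon means is `C[i,j]` = shared
root-to-tip branch length. With taxon-mean matrix `X` over `t` taxa,

    a = (1' C⁻¹ 1)⁻¹ 1' C⁻¹ X              (phylogenetic mean)
    R = (X − a)' C⁻¹ (X − a) / (t − 1)      (evolutionary covariance)

and the eigenvectors of `R` are the PC axes; individuals are projected onto
them to form morphospace clouds. On a star tree this reduces exactly to
ordinary PCA.

**TSV.** For draws `x ~ N(μ_T, σ_T)` per axis (5,000 Monte-Carlo draws per
taxon), divergence from a reference taxon with per-axis mean `μ_ref` and SD
`σ_ref` is

    TSV(x) = sqrt( Σ_k ((x_k − μ_ref,k) / σ_ref,k)² )

reported as mean ± SD over draws. Any taxon can serve as reference, which
supports native-vs-native contrasts.

**Conserved-gene normalization.** Genes with a coefficient of variation
≤ 0.3 across *all* samples of all species anchor a gene-wise median-of-ratios
scaling factor per species against a reference species; applying the factors
preserves all within-species expression ratios.

**Co-expression.** Unsigned adjacency `|cor|^β` with β chosen for
approximate scale-free topology, topological-overlap dissimilarity,
average-linkage clustering with a static branch cut (min module size 30),
eigengene = PC1 of each module, and a random-species-intercept mixed model
`eigengene ~ trait + (1|species)` with a likelihood-ratio p-value and
marginal R². Hub genes satisfy K_ME > 0.8 (correlation with the eigengene)
and GS > 0.2 (|correlation| with an associated trait).

**CLR sweep scan.** Per 2-kb window, the folded SFS is contrasted against
the genome-wide background spectrum under a hitchhiking "escape" model: a
sweep at the window midpoint lets each of n lineages escape with probability
`p_e = 1 − exp(−α·d)` at distance d; escapees plus one ancestral lineage
carry background variation (hypergeometric downsampling), hitchhikers copy
the ancestral lineage. `CLR = 2 ln(max_α CL(α) / CL(neutral))`, maximized
over a log-spaced α grid that includes the neutral limit, so CLR ≥ 0. Top-1%
windows are tested for enrichment in hub-gene regions against a
1,000-resample null (calls at the 95th/99th percentiles).

## Worked example

```bash
python examples/01_phenotype_divergence.py
```

prints (abridged):

```
                heart_ratio  myocyte_area  ...  myocyte_resid  capillary_resid
H_tree_sparrow         1.59         81.43  ...           0.27           429.51
L_tree_sparrow         1.34         52.44  ...          -0.08            25.97
RN_snowfinch           1.29         60.06  ...          -0.08          1344.72
WR_snowfinch           1.03         57.98  ...          -0.23          1520.88

TSV H_tree_sparrow vs L_tree_sparrow: 7.03 +/- 1.04
TSV RN_snowfinch vs L_tree_sparrow: 11.41 +/- 1.19
TSV WR_snowfinch vs L_tree_sparrow: 15.76 +/- 0.82
```

The group means carry the study's signature: only the recent colonizer
(H_tree_sparrow) shows cardiac hypertrophy (higher heart-mass ratio and
cardiomyocyte area), while the two natives instead raise capillary density;
the TSV values quantify each taxon's multivariate distance from the lowland
reference. The other examples cover normalization (`02`, recovering the
planted scale offsets 1.298/1.374), module and hub discovery (`03`), the
sweep scan (`04`), and outlier-in-hub-region enrichment (`05`). The same
stages are available as a CLI (`altadapt simulate|phenospace|normalize|
coexpr|sweep|enrich|run-all`).

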