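# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the known limitations of `bonenet`.

## Network model

The co-expression network is unsigned: adjacency `a_ij = |r_ij|^β` with
`r_ij` the Pearson correlation of genes i and j across strains. β is chosen
as the smallest candidate power (default grid 1–10, the standard range for
unsigned networks) whose connectivity distribution attains a scale-free
model fit R² ≥ 0.8 with negative slope; the fit regresses log10 bin
frequency on log10 mean connectivity over 10 equal-width connectivity bins.
If no candidate qualifies, the maximizing power is used and flagged. Both
the bin count and the R² target are configurable.

Topological overlap is

    ω_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu,

with ω_ii ≡ 1. The matrix implementation (one matrix product) is checked
against a literal triple-loop evaluation to 1e-10 on instances up to 50
genes. The denominator is at least 1 − a_ij ≥ 0; an all-zero adjacency gives
ω = 0 off-diagonal.

### Branch cutting

Modules are branches of an average-linkage dendrogram of `d = 1 − ω`. The
published analyses this package emulates use the Dynamic Hybrid branch
cutter; `bonenet` implements a simplified two-stage cut whose adequacy is
defined by the module-recovery tests rather than by algorithmic fidelity:

1. static cut at 0.99 of the maximum merge height;
2. recursive splitting of any branch whose root merge sits more than 0.1
   (in `d` units) above its children's merges, when both children are at
   least the minimum module size;
3. dissolution of clusters below the minimum size (default 20) to label 0;
4. a kME membership pass: members whose kME to their own eigengene falls
   below 0.3 are unassigned, and unassigned genes whose best |kME| reaches
   0.5 join that module. The thresholds sit several null standard
   deviations (kME sd ≈ 1/√n ≈ 0.1 at n = 96) below the loadings the
   generator plants (0.6–0.9), so the pass removes weakly attached leaves
   without inventing membership. This kind of kME-based cleanup is standard
   practice in weighted co-expression analysis.
5. eigengene-based merging: module pairs with eigengene dissimilarity
   (1 − correlation) below 0.25 are merged iteratively and eigengenes
   recomputed. The merge threshold is a free parameter of the method (no
   canonical value exists); 0.25 is the common default.

Labels are renumbered by descending size; 0 means unassigned. On the default
synthetic scale the partition recovers planted modules with mean adjusted
Rand index ≈ 0.98 and leaves pure-noise expression ≥ 90% unassigned.

### Eigengenes and kME

Module eigengenes are first-principal-component scores over strains of the
row-standardized module submatrix, scaled to unit variance and oriented so
the mean member correlation is ≥ 0 (an exactly antipodal tie falls back to
orienting along the first member). Variance explained is s₁²/Σs² of the
singular values. kME is the signed Pearson correlation of every gene with
every module eigengene. Probes are never collapsed to genes.

Missing expression values are handled by pairwise-complete correlation;
genes with more than 20% missing values are dropped with a log entry.
Zero-variance genes get correlation (and GS) 0 with a warning.

## Marker-anchored significance

Gene Significance is the absolute correlation with the eigengene of a
user-supplied marker set (the osteoblast/osteocyte markers in the bone
application; the generator plants a 9-gene subset of the target module).
Module Significance is the exact mean member GS. Its null draws
module-sized GS sets without replacement from the pool of module-assigned
("network") GS scores — not from all genes — 10,000 times by default, and
counts draws whose mean is strictly greater than the observed MS. That
counting rule can return p = 0; the report annotates such values as
"< 1/n_perm" and carries a conservative (count+1)/(n_perm+1) estimate in a
separate column. Significance is flagged at 0.05 / n_modules.

The cell-type contrast takes, per gene, the maximum over the target cell
type's time-point means minus the mean over all other samples, averages over
module members, and uses the same gene-resampling null (with ≥ counting,
since ties are possible in principle). Genes are matched between network
and reference by identifier.

## Mixed-model association

The model is y = Xβ + u + e with var(u) = σ_g² K and var(e) = σ_e² I.
Kinship is the identity-by-state proportion over SNPs (the estimator is not
dictated by the method; IBS is the simplest consistent choice for a binary
inbred panel), with a 1e-6 ridge if numerically indefinite. REML profiles
the restricted likelihood down to δ = σ_e²/σ_g² through one
eigendecomposition of S(K+I)S (S the covariate-projection complement),
maximizes over log δ on a 100-point grid spanning [−10, 10] and refines
every interior grid maximum with bounded 1-D optimization; boundary optima
are reported as such. Pseudo-heritability is 1/(1+δ).

Per-SNP tests rotate y, X and the genotypes by the kinship eigenbasis
scaled by (λ + δ)^{−1/2} and run ordinary regression on the rotated data —
a two-sided t-test on the SNP coefficient with n − rank(X) − 1 df. Null
variance components are estimated once per response and reused for all SNPs
(the EMMAX-style approximation); exact per-SNP re-estimation is available
via `per_snp_reml=True`. With K = I the scan reduces to OLS exactly
(verified to 1e-8), and the simulated null type-I error at α = 0.05 is
0.05 ± 0.02. Zero-variance SNPs are reported with p = 1 and flagged.
Genome-scale eQTL scans stream one probe at a time, sharing the spectral
decomposition across probes, and record per-bin minimum p-values without
ever materializing more than one probe's full scan.

Local-eQTL tables test probes annotated inside a region against SNPs inside
the same region, keep the most significant probe per gene, and apply a
Bonferroni threshold of 0.05 / n_unique_genes_in_region.

## Hotspots

The genome is tiled into half-open 5-Mb bins (1-based starts, last bin
truncated). A probe is a hit in a bin when its bin-minimum association
satisfies −log10 p ≥ 4; a probe can hit several bins. Each bin's 2×2 table
(module hit/miss vs background hit/miss) gets a one-sided (enrichment)
Fisher's exact p — the question is over-representation of module eQTL, so a
directional test — with a Bonferroni flag at 0.05 / n_bins. Bins created by
tiling that contain no SNPs carry no minima and report p = 1.

## Causal orientation

For a triad (M marker genotype, A candidate expression, B module
eigengene), each of the three path models imposes exactly one constraint on
the correlation matrix, equivalent to a vanishing partial correlation:
causal M⊥B|A, reactive M⊥A|B, independent A⊥B|M. Fitting the path model by
maximum likelihood to the standardized (correlation) matrix gives the
closed-form deviance chi² = −(n−1)·ln(1 − r_partial²) on 1 df, because the
ML-fitted covariance matches the sample covariance on the model's cliques
and the trace term equals 3 exactly. The package uses the closed form; an
independent iterative minimizer of the ML discrepancy
F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − 3 over the two path coefficients is provided
and agrees to better than 1e-6 in chi² (a mutual-oracle test). Correlation
rather than covariance matrices are fit; the marker enters as numeric 0/1.

LEO.NB = log10 p_causal − log10 max(p_reactive, p_independent), with
p-values floored at 1e-300 before the ratio (floor usage is flagged) and a
log10 base throughout. Scores above 1.0 are treated as strong support for
the causal orientation. Candidate tables report, per gene with a
significant local eQTL in the region: the eSNP p, the percentage of module
genes correlated with the candidate at |r| strictly greater than 0.25, the
eigengene correlation, and LEO.NB against the lead module-QTL SNP; the
maximum-score candidate is flagged.

## Trait link and perturbation concordance

The module eigengene is regressed on (trait, trait²); significance is the
overall F-test against the intercept-only model (the fit is summarized by a
single p; per-coefficient t-tests are also emitted). Percent differences
follow fixed denominators: panel differences use the named reference
genotype group's mean, perturbation differences use the perturbed mean —
the latter is an unusual denominator but is kept for fidelity with the
convention this analysis style uses. Per module, the Pearson correlation
between the per-gene panel and perturbation difference vectors (with its p
and a 0.05/n_modules flag) measures whether the same genes respond to the
genotype and to the perturbation.

## Enrichment

Fisher's exact (one-sided) and a sampling null: n_draws random gene sets
drawn uniformly without replacement from the universe (Floyd's algorithm),
p = fraction of draws whose overlap with the fixed set reaches the observed
overlap. The smaller of the two sets is drawn; the overlap law is
hypergeometric and symmetric in which set is drawn, which the tests verify.
The universe is always an explicit argument because the choice (all
network-input genes vs module-assigned genes) changes the answer.

## Synthetic study design

The generator plants, with recorded ground truth and full seed
determinism:

* **Genotypes** — 96 fully homozygous strains (codes {0,1}; heterozygotes
  are out of model for an inbred panel), each chromosome a mosaic of 8
  founder haplotypes with Poisson breakpoints at one expected crossover per
  30 Mb. This induces local LD and realistic kinship without
  population-genetic machinery. SNPs below a 5% MAF floor have founder
  alleles redrawn; an unattainable floor raises an error.
* **Expression** — 2,000 probes on a 2×100 Mb genome; 10 modules of 40–120
  genes driven by latent strain factors; gene g of module m is
  `λ_g·F_m + √(1−λ_g²)·ε` with λ_g ~ U(0.6, 0.9) and unit noise, on top of
  a per-gene baseline abundance ~ N(8, 1) (log2 scale). The √(1−λ²) noise
  scaling makes λ_g the gene–factor correlation at unit noise (so
  within-module correlations are λ_iλ_j ≈ 0.35–0.8); with unnormalized
  noise the planted correlations would be too weak to separate modules at
  the fixed association thresholds the analysis inherits.
* **Driver** — one target-module gene is relocated next to a common SNP
  (MAF ≥ 0.3) and simulated as `γ·g_cis + ε` with γ = 3 (cis h² ≈ 0.7).
  The target module's factor is
  `(θ·z_driver + (1−θ)·f)/√(θ²+(1−θ)²)` with θ = 0.5, so half the
  (normalized) factor weight flows through the driver. The common-SNP
  restriction and γ exist so that the planted trans-hotspot clears the
  fixed −log10 p ≥ 4 hit rule with high probability at n = 96; a rare cis
  allele would make the planted architecture undetectable by construction,
  which is a statement about power, not about the method.
* **Trait** — the trait t is sampled first (standard normal) and the
  module-driving factor is curvature·(t − vertex)² plus noise,
  standardized; the eigengene is therefore quadratic in the trait by
  construction (vertex 0, curvature 1, unit noise by default), and
  curvature = 0 yields an exactly null link.
* **Cell-type reference** — 4 cell types in triplicate; the target type has
  three time points with elevations 0.6/0.8/1.0 × the nominal log2
  elevation (default 2), so the max-over-time-points rule is exercised;
  assay noise sd 0.25.
* **Knockdown** — re-simulation with the same seed (identical noise
  stream), the driver-module coupling scaled by 0.5 and the standardized
  driver signal shifted down by 1.5, plus small (sd 0.1) independent assay
  noise so uncoupled genes still vary between conditions.
* **External gene list** — 57 genes, 9 from the target module, the rest
  random; the composition gives the target module a clear but not extreme
  enrichment (p ~ 1e-3 against a ~4.5% module fraction), mirroring a
  marginal-but-decisive GWAS-homolog signal.

What the generator does *not* emulate: probe-level artifacts (multiple
probes per gene, cross-hybridization), expression heteroskedasticity,
population structure beyond the founder mosaic, sex chromosomes,
recombination hotspots, selection, and trait architectures beyond the
single quadratic link. Passing recovery tests therefore demonstrate that
the pipeline's inference chain is correct under its own statistical
assumptions, not that those assumptions hold in any particular real panel.

## Problem sizes used by tests and the acceptance script

The default study scale (96 strains, 2,000 genes, 10 modules, 1,000 SNPs)
was chosen so a full pipeline run takes seconds on one CPU. The acceptance
suite runs 50 end-to-end recovery seeds and 40 curvature-0 null seeds at
that scale with 1,000 MS permutations per seed (permutation resolution
0.001, finer than the 0.005 flagging threshold, so the flagging decision is
unchanged relative to the 10,000-draw default); the acceptance script
aggregates 20 recovery and 20 null seeds and 100 null mixed-model scans.
Unit tests use a 400-gene, 4-module, 300-SNP panel.

## Known limitations

* The branch cutter is a deliberate simplification of dynamic hybrid tree
  cutting; very close module pairs (eigengene correlation > 0.75) merge by
  design, and modules weaker than the kME thresholds dissolve.
* The EMMAX-style single variance-component estimate slightly miscalibrates
  p-values for SNPs with very large effects; exact per-SNP REML is
  available but ~m times slower.
* LEO.NB with a single marker cannot distinguish causal from reactive when
  the marker is weak (both constraint tests lose power simultaneously).
* The permutation nulls resample genes, treating them as exchangeable;
  correlated genes make these nulls mildly anti-conservative, which is
  inherent to the resampling scheme rather than to this implementation.
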