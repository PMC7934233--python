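# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `sceqtl`.

## Pipeline model and assumptions

**QC.** Four per-cell metrics (library size, genes detected, % mitochondrial,
% ribosomal counts) are screened two ways: a two-sided cut at k = 3 scaled
MADs (scale factor 1.4826, normal-consistent) from the metric median, and
fixed thresholds (% mito > 20, % ribo > 50, strict inequalities). Library
size and detected-gene counts are log1p-transformed before the MAD cut —
these metrics are strongly right-skewed and the raw-scale MAD over-flags the
right tail; the log transform is the convention of the R single-cell QC
ecosystem (scater's `isOutlier`). Percent metrics are cut on their raw
scale. A metric whose MAD is zero removes no cell (degenerate-spread guard),
and `k = inf` disables the MAD filter. Every filter is evaluated exactly
once on its full input; there is no iterative re-filtering. Cell filters run
first, then the supplied mito/ribo gene sets are discarded (so those
abundant genes cannot dominate normalization), then genes detected in < 1%
of the retained cells are dropped (strict). MAD filtering is applied
globally per dataset, not per pool. Re-applying the full QC to its own
output is *almost* a fixed point: threshold and prevalence rules are exactly
idempotent, but MAD bounds re-estimated on the filtered distribution can
trim a residual sliver (< 1% in practice); the test suite asserts the
bounded version.

**Pseudobulk and normalization.** The eQTL response is the per-donor,
per-cell-type mean of QC'd raw counts (donors with zero cells of a type are
absent from that type's matrix). Quantile normalization maps each donor row
to the across-donor mean order statistics — rows become permutations of one
reference distribution; tied values receive the mean of the reference values
the tie spans. The z-transform then standardizes each gene across donors
(sample SD, n−1); zero-variance genes are set to zero and flagged. The
normalization axis matters: donor-rows-to-common-distribution makes the
per-gene z-step non-redundant and, importantly, removes any donor-global
multiplicative shift exactly (such a shift leaves within-donor ranks
unchanged), which is what keeps downstream tests calibrated in the presence
of donor random effects. Pseudobulk means are computed on raw QC'd counts;
cell-level normalization between pools/batches is out of scope here.

**Latent factor.** The hidden-confounder covariate is the top left singular
vector of the z-stage matrix, standardized to mean 0 / SD 1, with the sign
fixed so the largest-magnitude gene loading is positive (deterministic
output). One-factor PEER is close to probabilistic PCA, so the top SVD
factor is used as a named substitution for a variational PEER fit; it is
computed per cell type on all QC-passing genes.

**Association.** OLS of z-expression on [1, dosage, factor], dosage coded
as 0/1/2 copies of the **reference** allele and used unstandardized (β is
per allele copy on the z scale). Two-sided p from the t distribution with
n − p degrees of freedom. Pairs are all same-chromosome SNPs with position
in [gene start − 1 Mb, gene end + 1 Mb] (1-based, inclusive) and MAF
strictly above 0.05, MAF being computed on the post-QC analysis donors. The
batch fitter residualizes expression and dosage against [1, covariates]
(Frisch–Waugh) and is numerically identical to the single-pair fit; pairs
with a constant dosage are skipped and logged. BH q-values are computed
study-wide — all (cell type, gene, SNP) tests of a dataset pooled into one
step-up run, the stricter reading of a study-wide FDR — and records with
q < 0.10 are significant. Top eSNP per significant gene: lowest p, ties by
largest |β|, then smallest position. Missing genotypes are not modeled; the
VCF reader drops multi-allelic records and records with any missing GT, with
logged counts.

**Five-way model comparison.** `compare_models` reproduces the comparison
that motivates the pseudobulk + 1 factor default: pseudobulk with 0, 1 or 10
latent factors, and two cell-level models (quantile-normalized/z expression,
and raw counts) with a donor random intercept fit by maximum likelihood
(statsmodels MixedLM; Wald test on the dosage effect). The random intercept
absorbs the non-independence of cells from the same donor; a naive
cell-level OLS that ignores it is anticonservative, which the test suite
demonstrates under strong donor confounding. Ten factors are skipped with a
warning when donors ≤ 12.

**Specificity battery.**
* *Sharing*: an eGene is `unique` (one cell type), `ubiquitous` (all cell
  types), `shared_same_eSNP` (two of its cell types share a significant
  eSNP, or their top eSNPs have r² ≥ 0.2), else `shared_different_eSNP`.
  LD r² is the squared Pearson correlation of dosages (composite LD).
* *Conditional independence*: `G_a ~ 1 + S_a + S_b + factor`; the pair is
  independent when the S_a coefficient has p < 0.05 (configurable nominal
  alpha; the threshold is not stated by the convention this follows).
  Both directions are tested and a pair-level call requires both to retain
  significance; collinear pairs (r² = 1) are flagged untestable.
* *Interaction*: for eGenes significant in ≥ 2 cell types, the candidate
  eSNP must be significant in both cell types of the pair and the pair with
  the largest |β difference| is tested (ties by smaller p). Restricting
  candidates to doubly-significant pairs matters: maximizing a noisy β
  difference over all tested eSNPs is a winner's-curse selection that would
  flag truly shared eGenes. The test stacks donor × cell-type rows (each
  row carrying its own cell type's factor value) and compares nested OLS
  models without/with the S·C term by the 1-df F-test, which equals the
  squared Wald t. BH across tested eGenes at FDR 0.05. Donor
  non-independence across a donor's two rows is ignored by construction
  (plain linear model + anova); this stays calibrated here because quantile
  normalization removes the donor-global component of the random intercept,
  leaving the two rows' residuals essentially uncorrelated — with a noise
  model in which donor effects are *not* gene-uniform, the test would be
  conservative.
* *Enrichment*: genes ranked ascending by their best cis p-value in the
  target cell type; observed statistic = mean rank of the source cell
  type's eGenes; null = mean ranks of 10,000 random same-size gene sets;
  p = P(T ≤ (obs − null mean)/null SD) with a t reference on n_perm − 1 df,
  one-sided toward enrichment (low ranks). Sidedness and the exact t-test
  variant are design choices.
* *Scenario labels*: `assign_scenarios` combines the battery with the
  precedence unique → `specific`; shared-different + independent (both
  directions) → `independent_loci`; significant interaction →
  `interaction`; else `shared`. Independence is checked before the
  interaction test because a gene driven by distinct loci in different cell
  types also produces a genuine interaction signal at either locus.

## Synthetic-data generator

The generator emulates a multi-donor, multi-cell-type 10x-style experiment
at desk scale.

*Genotypes*: per SNP, a reference-allele frequency is drawn from
`maf_range`; two haplotypes per donor are independent Bernoulli draws and
dosage is their sum. LD blocks are made by haplotype copying — within a
block each SNP copies the previous SNP's haplotype with probability
`copy_prob` per haplotype, else redraws — giving adjacent correlation
r = copy_prob with a two-line Monte-Carlo oracle (and r² = copy_prob² per
step), rather than a full coalescent.

*Counts*: cell i, gene g ~ NB(mean = s_i · exp(b_g + u_d + β_log·dosage),
dispersion θ) with variance μ + μ²/θ, sampled as Gamma–Poisson. s_i is a
log-normal cell scaling factor (default σ = 0.35), b_g ~ Normal(−0.7, 1) on
the log scale, and u_d ~ Normal(0, donor_sd²) (default 0.3) is shared across
all of a donor's cells in every cell type — the non-independence the
random-intercept models address. Mito/ribo gene subsets are rescaled so
their expected count share is 6% / 18%, making the QC percentages
non-trivial. Planted outlier cells get a 12× scaling-factor inflation.
Defaults are chosen for statistical realism at desk scale (a ~100–400 gene
"transcriptome", per-cell library ~10²), not to match any particular
dataset; absolute library sizes are therefore small, but the noise
*structure* (NB overdispersion, log-normal libraries, donor random effects,
LD) is the part downstream inference is sensitive to. Doublets, ambient
RNA, batch effects and read-level data are not emulated, so passing tests
say nothing about demultiplexing or batch robustness on real data.

*Planted effect sizes.* `EffectSpec.beta` is in z-transformed-expression
units per reference-allele copy — the scale the association model actually
fits — while the mechanism plants an additive coefficient on the log-mean
scale. The bridge is a deterministic calibration: given the realized dosage
vector, the solver finds the log-scale coefficient whose implied z-scale
regression slope equals the requested β, accounting for (i) the exponential
mean function evaluated exactly at the three dosage values, (ii) the
relative noise left after averaging NB counts with log-normal cell factors
over the cells of a donor, and (iii) the removal of the donor-global
intercept by quantile normalization. Requests beyond the reachable slope
(possible for very lowly expressed genes, where the noise floor caps the
standardized effect) raise an error rather than silently clipping.
`expressed_genes` returns the natural planting targets: regular genes
between the 40th and 90th base-expression quantiles — the lower bound
avoids the noise-floor cap, the upper bound avoids the extreme top ranks
where quantile normalization is locally degenerate (the maximal gene ranks
last in every donor, so its across-donor variation is flattened). Planting
on expressed genes mirrors real studies, which map eQTLs only for detected
genes. Residual calibration error is small but nonzero: QC attrition
(~4–6% of cells at defaults) and rank-mapping noise at a few hundred genes
bias recovered β downward by ~2–4%, within the ±5% recovery tolerance the
package tests.

*Randomness*: one integer seed feeds `numpy.random.SeedSequence`, which is
split into independent streams per operation (genes, donors, cells, counts,
outliers), so fixtures are bit-reproducible and `base_log_means` can expose
the gene means planners need without perturbing the count stream.

## Reference study conditions (`sceqtl.benchmarks`)

The benchmark harnesses fix the study conditions used by the test suite and
the acceptance script:

* **Null calibration** — 80 donors, 6 cell types, 200 genes, 2000 SNPs,
  50 cells/donor/type, all betas zero. Uniformity of cis p-values is tested
  by KS on one randomly chosen SNP per (gene, cell type): cis pairs of one
  gene share its expression vector and are strongly dependent, and the KS
  test requires independent observations. Study-wide FDP is averaged over
  seeds (under a global null any rejection is false, so per-seed FDP is the
  any-rejection indicator). Interaction type-I error is estimated from
  random (gene, SNP, cell-type pair) picks at nominal α = 0.05.
* **Parameter recovery** — one planted cell type-specific effect
  (β = 1.0) per replicate, 80 donors, 2 cell types, 100 cells/donor/type,
  400 genes (enough genes that quantile normalization's finite-gene
  discretization is negligible), 40 SNPs spread widely so the cis test
  burden stays moderate.
* **Scenario panel** — 80 donors, 3 cell types, 100 cells/donor/type,
  200 genes, 400 SNPs in 3-SNP LD blocks (copy_prob 0.7), 20 genes per
  scenario at the default effect size β = 1.0 (interaction scenario:
  ±1.0). The default β was set with the independence test's operating
  characteristics in mind: at β = 1.0 the pair-level call keeps both the
  true-positive rate on genuinely independent loci and the true-negative
  rate on r² ≈ 0.9 LD proxies of a single shared locus above 95%.
* **Independence replicates** — 3-SNP blocks with copy_prob 0.974, so the
  two proxies flanking the causal SNP have r² ≈ 0.9 with each other.

## Numerical choices

* OLS is solved by `numpy.linalg.lstsq` (single pair) and by QR
  residualization + cross-products (batch); both agree with the
  normal-equations solution to ~1e-12 and with each other to 1e-10.
* BH q-values: sort, multiply by m/rank, reverse cumulative minimum, cap at
  1; stable (mergesort) ordering makes ties deterministic.
* Zero-residual degeneracies (constant genes) yield p = 1 for β = 0 and
  p = 0 otherwise, rather than NaN.
* All file writes are atomic (temp file + `os.replace`): a crash never
  leaves partial outputs.
* Coordinates are 1-based inclusive; dosage counts reference alleles,
  the opposite of the common ALT-dosage convention, and the VCF reader and
  writer are tested against a hand-coded fixture.

## Known limitations

* The interaction and independence models treat pseudobulk rows as
  independent across cell types; gene-specific donor effects (not emulated
  by the generator, which makes donor effects gene-uniform) would make the
  interaction F-test conservative.
* PEER is approximated by one SVD factor; with k ≫ 1 the approximation to
  PEER's variational posterior degrades.
* Hard genotype calls only; no dosage uncertainty, no missing genotypes,
  no trans-eQTLs.
* The sharing classification depends on the significance threshold in the
  usual discrete way: an effect hovering at the FDR boundary can flip an
  eGene between `unique` and `shared` categories between runs.
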