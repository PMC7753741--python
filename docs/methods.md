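# Methods

`parallodrome` implements two complementary lines of inference on paired
foothill/alpine population samples of a mixed-ploidy plant: a genetic test
of whether the alpine ecotype arose once or repeatedly, and a
quantification of how parallel the phenotypic response to the alpine
environment is, separating heritable from plastic components with a
common-garden contrast.  A synthetic-study generator with known ground
truth stands in for raw field data and drives the recovery tests.

## Coalescent simulator

The simulator is a multi-deme Kingman coalescent with deterministic
demographic events (deme merges, migration-rate and size changes) and
backwards-in-time lineage migration.

**Scaling.** Time is measured in coalescent units of 2 N0 generations for
a reference size N0; deme sizes are dimensionless multiples of N0, so a
deme of size N coalesces each lineage pair at rate 1/N.  Migration rates
are per lineage per time unit.  Mutations are dropped on branches as
Poisson(theta/2 x branch length) under infinite sites, so theta = 4 N0 mu
per locus and two lineages in a size-1 deme accumulate theta differences
in expectation.  The cross-engine tests match this to msprime by setting
each msprime population's size to N/2 (diploid bookkeeping halves the
per-pair rate) and the mutation rate to theta/2, after which msprime
"generations" coincide with our coalescent units.

**Ploidy.** Autotetraploid individuals are four exchangeable lineages
(polysomic inheritance; double reduction is ignored as second-order and
unidentifiable at these sample sizes), diploids two.  All downstream
statistics count lineages, so mixed-ploidy samples need no special
casing.

**Loci.** Loci are unlinked (free recombination between, none within).
Genotype matrices use either Poisson mutation counts per locus or a
one-segregating-SNP-per-locus mode in which the mutation lands on a
branch drawn proportionally to its length — the structure of RAD data
thinned to one SNP per 150-kb window.  Each locus occupies its own
window, so per-window thinning is idempotent on simulated data by
construction.

**Performance.** The per-genealogy event loop is compiled with numba;
a 20,000-replicate expected spectrum for 32 lineages in 4 demes takes
about 0.15 s, which is what makes simulated-likelihood model comparison
tractable on one CPU.

## Origin test

For a pair of regions (one alpine and one foothill population each) four
candidate histories are compared: P (alpine and foothill demes of a
region are sisters — parallel origin), S (demes of the same ecotype are
sisters — single origin), and PM/SM, the same topologies with a
within-region alpine<->foothill migration epoch from time 0 to the first
merge.  Migration connects only the two demes of a region, mirroring the
candidate histories' secondary-contact arrows.

The observable is the unfolded 4-dimensional joint allele frequency
spectrum (folded when no ancestral-allele annotation exists; corners
masked).  Observed spectra from genotype matrices are down-projected
hypergeometrically to configurable per-population lineage counts
(default 8) to keep the 4-D grid small.

Fitting maximizes a multinomial composite log-likelihood
sum_c O_c ln E_c over unmasked cells, with the expected spectrum E
estimated by branch-length-weighted Monte Carlo (20,000 replicate
genealogies per evaluation by default) and floored at 1e-12 so
Monte-Carlo zeros cannot produce -inf.  Multinomial rather than Poisson
composite likelihood is used because the artifact does not model the
invariant-site count a Poisson intensity would need.  The optimizer is
Nelder-Mead over log-transformed parameters — shared deme size N,
T_within, the increment T_root - T_within (which enforces the time
ordering), and m for PM/SM, so k = 3 or 4 — with common random numbers
(fixed per-fit simulation seeds) making the likelihood surface
deterministic, and three jittered restarts.  The parameterization is
deliberately minimal: the analysis is a model-class comparison, not
parameter estimation, and parsimony serves that purpose.  Scenarios are
ranked by AIC = 2k - 2 loglik and Akaike weights.

## Population-genetic statistics

* **pi** — per-locus n/(n-1) x 2pq summed or averaged over loci; the
  reported value is **per SNP** (mean over the loci in the matrix), not
  per site: converting to per-site diversity needs the callable
  invariant-site count, which a SNP matrix does not carry.  Missing
  genotypes are excluded pairwise per locus.
* **Tajima's D** — standard constants computed from the total lineage
  count (a 4-individual tetraploid population enters with n = 16);
  undefined (NaN with a warning) when S = 0.
* **FST** — Hudson's estimator as a ratio of averages over loci,
  chosen as the low-bias default for unequal sample sizes; the module
  boundary would admit a Weir–Cockerham alternative.
* **AMOVA** — Excoffier-style variance components from mean squares of
  squared Euclidean distances between individual allele-frequency
  vectors (dosage/ploidy), with the standard unequal-size coefficients;
  negative components are truncated to zero before percentages.
  Permutations: whole populations across groups for the among-group
  component, individuals across populations within their group for the
  second level.
* **Clustering** — PCA on centered individual allele frequencies
  (mean-imputed missing cells), then K-means with many random starts per
  K and BIC(K) = n ln(WSS/n) + K ln(n) on the leading axes explaining
  90% of variance (configurable; the criterion follows the
  find.clusters convention).  Ties across starts break to the lowest
  seed index for determinism.  Note this BIC overfits when true
  within-cluster variance is tiny relative to separation in few
  dimensions; with the noise-dominated many-axis scores of genotype
  data it is well behaved.
* **Tetraploid subsampling** — two alleles drawn hypergeometrically per
  tetraploid genotype, which preserves expected allele frequencies and
  lets diploid-oriented clustering run on mixed-ploidy data.

## Phenotype statistics

**Preprocessing.** Population-mean imputation of missing cells, then
derivation of four shape ratios from the untransformed organ
measurements, then natural-log transform of every column except the four
flower-organ measurements (codes PL, PW, SL, SW), which are treated as
already near-normal.

**Multivariate tests.** PCA on standardized traits; one-factor PERMANOVA
with pseudo-F on Euclidean distances and 30,000 label permutations by
default (p = (#{F_perm >= F_obs}+1)/(n_perm+1)); disparity as the median
distance of individuals to their own-group centroid using all ordination
axes (a parameter-free default; axis subsets are an argument away), with
a one-way ANOVA on the individual distances.  Linear discriminant
analysis with equal priors provides constrained ordination (loadings are
sign-arbitrary) and classification success, cross-validated leave-one-out
— deterministic, with no fold-seed dependence.

**Per-trait mixed models.** Each trait is fitted as
y = ecotype * region + (1 | population) by REML: the variance ratio
lambda = sigma_u^2/sigma_e^2 is profiled by 1-D bounded optimization,
with the boundary lambda = 0 checked explicitly; for a given lambda the
GLS solve reduces to a per-population shrink of the block mean
(V = I + lambda Z Z' is block diagonal), so each criterion evaluation is
one least-squares fit.  Fixed effects are tested by sequential (Type I)
F-tests in the order ecotype, region, interaction against the REML
residual mean square, with containment denominator degrees of freedom
(populations minus ecotype x region cells) since the tested effects vary
at the population level.  When lambda = 0 these tests collapse exactly
to OLS ANOVA.  Effect sizes are partial eta-squared,
SS_effect/(SS_effect + SS_residual), from Type II sums of squares of the
fixed-effects model on individual data.

**Parallelism calls.**  With alpha = 0.05 per test and no multiplicity
correction (a Benjamini–Hochberg flag exists but is off by default, for
fidelity to the conventional per-test significance the decision rules
assume):

1. interaction significant in **both** datasets -> `nonparallel_genetic`
   (a significant ecotype x region interaction marks non-parallelism
   regardless of the ecotype main effect — this precedence is a design
   choice for the case where both are significant);
2. ecotype significant and interaction non-significant in **both**
   datasets -> `parallel_genetic`;
3. ecotype or interaction significant in the field but neither in the
   garden -> `plastic`, sub-typed `nonparallel_plastic` when the field
   signal included the interaction;
4. otherwise `none`.

Each call keeps its evidence (p-values, effect sizes) and the effect-size
plane coordinates (eta2 of the interaction on x, eta2 of ecotype on y)
with strict-inequality above-diagonal flags (ties are "not above").

## Synthetic-study generator

The generator emulates the study design the analyses assume: five
mountain regions (NT, VT, ZT, RD, FG), VT diploid and the rest
autotetraploid, each with three foothill and three alpine populations of
~17 phenotyped (4 genotyped) individuals; the common garden covers four
regions x two populations per ecotype x 14 individuals.

**Genotypes** follow a parallel-origin demography: populations split from
their region x ecotype deme at T_pop = 0.01, the alpine deme of each
region splits from its foothill deme at T_within = 0.05, and regions
split star-like from the common ancestor at T_root = 0.5, all demes the
same size (no alpine bottleneck).  The deep-between/shallow-within
contrast produces regional (not ecotypic) clustering, a region-dominated
AMOVA and overlapping per-ecotype diversity — the qualitative genetic
results the pipeline should recover.  T_pop is not zero so that
populations are distinguishable, but well below T_within so within-region
structure stays shallow.

**Phenotypes** follow, on the generating scale, the same linear model the
analysis fits: mu + alpha [alpine] + beta_region + gamma_region [alpine]
+ pi [alpine][field] + u_pop + eps, with u_pop drawn once per
(population, trait).  Log-scale traits are exponentiated to positive
measurements; the four log-exempt flower organs are generated directly on
the measurement scale so that the model analyzed is the model generated.
The default 16-trait registry (12 organs + 4 ratios) realizes 6 parallel
(stem height, floral organs, petal ratio), 6 plastic (leaf and sepal
sizes and their ratios; field-only effects), and 4 genetically
non-parallel traits (leaf lobe traits and stem leaf with an FG-region-
specific gamma, plus the lobe-depth ratio) — the regional leaf-lobe
signal carried by one region mirrors the qualitative field/garden
pattern.  Effect magnitudes were set by the power analysis in
`scripts/calibrate_traits.py` so that every class-defining test has
roughly >= 0.9 power per dataset at the default design while null tests
stay at nominal alpha; with per-test alpha = 0.05 and four tests per
trait, a median of ~15/16 correct calls per study is the practical
ceiling, and the recovery requirement is >= 14/16.

**Environment** tables shift all eight variables by ecotype (alpine
sites colder, brighter, wetter, less vegetated) with no regional effect
and independent population noise whose SDs keep all pairwise |r| <= 0.8;
the table is regenerated on the rare draw that violates the screen.

**What the generator does not emulate:** linkage within RAD loci, allele
dropout and genotyping error, selection, drift-induced phenotype-genotype
correlation (phenotypes and genotypes are generated independently given
the design), maternal effects in the garden generation, and
trait-trait residual correlations beyond those induced by shared ratio
components.  Passing recovery tests therefore demonstrate that the
statistical machinery recovers its own generating model at realistic
effect sizes and sample sizes — not that real data would behave as
cleanly.

## Problem sizes and numerical choices

Recovery runs use desk-scale sizes chosen to keep the full suite
comfortable on one CPU: 5,000-SNP spectra with 8 lineages per population
and 20,000 Monte-Carlo replicates per likelihood evaluation for the
origin test; 3,000 post-filter SNPs and 100 K-means starts for the
clustering scan; 500 replicates for the neutral Tajima's D check; 20
replicate studies for classifier recovery.  Monte-Carlo tolerances in
tests are 3 standard errors unless an exact oracle applies (1e-10 for
closed-form statistic comparisons, 1e-6 for the LMM/OLS collapse).  Nelder-Mead uses xatol 0.02 on log parameters and soft
bounds |log parameter| <= log(1000); expected-spectrum cells are floored
at 1e-12.  Permutation p-values use the +1 convention, which makes them
discrete; uniformity tests therefore apply a randomized PIT before
Kolmogorov–Smirnov.

## Known limitations

* Composite-likelihood AIC treats SNPs as independent; with linked data
  the weights would be overconfident.  The generator's unlinked loci
  match the assumption.
* pi is per SNP, not per site; values are not comparable to
  resequencing-based diversity without an invariant-site denominator.
* The LMM's F-tests use containment df — a convention; other df
  approximations (Satterthwaite, Kenward–Roger) would differ slightly in
  small designs.
* The coalescent supports at most the 4-population spectra the origin
  test needs; growth, bottlenecks and within-locus recombination are out
  of scope.
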