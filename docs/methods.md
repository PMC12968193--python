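# Methods

`durumgp` implements a multi-trait, multi-environment genomic-prediction
workflow for replicated plant-breeding trials, exercised end to end on a
built-in synthetic generator that emulates a durum-wheat sowing-date panel.
This note records the models, the numerical choices, and what the synthetic
experiments do and do not establish.

## Stage 1: plot-level adjustment

Per environment and trait, plot values follow

    y_sjr = mu + Gen_s + Rep_j + Block_r(Rep_j) + e_sjr

The model is fitted twice, in the standard two-stage fashion:

* **genotype fixed** (cell-means coding), with replicate and
  block-within-replicate as random intercepts, to produce per-line adjusted
  means (BLUEs) on the trait scale with GLS standard errors;
* **genotype random**, otherwise identical, to estimate the variance
  components (sigma_g^2, sigma_rep^2, sigma_block^2, sigma_e^2) behind the
  broad-sense heritability.

REML is computed by a compact Woodbury-based solver (`adjust.reml_fit`) that
profiles the fixed effects and residual variance and optimises the log
variance ratios by L-BFGS-B (tolerance 1e-8 on the objective, at most 200
iterations, Nelder–Mead polish on abnormal line-search exits, boundary
estimates reported as zero).  A dedicated solver was preferred over
`statsmodels.MixedLM` because the genotype-random refit crosses a
many-level random factor with the nested replicate/block factors, which
MixedLM only handles through a slow single-group variance-component
workaround; the solver is cross-checked in the tests against lme4 (through
Rscript) on an unbalanced fixture and against closed-form balanced-design
identities.

Heritability is reported on the entry-mean basis by default,

    h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r),

with `r` the harmonic mean of per-line replicate counts; a plot-basis
variant (`method="plot"`) and the Cullis variant
(`method="cullis"`, 1 − v̄/(2σg²) from the mean variance of a genotype-BLUP
difference) are available.  A design with a
single replicate and a single block cannot separate anything from residual
noise and falls back to plain means with a warning.

## Stage 2: relationship kernels

**Genome-wide kernel (G).**  Dosages are filtered (per-marker missingness
<= 0.2, minor-allele frequency >= 0.01, both configurable), missing calls
imputed to the marker mean, and

    G = Z Z' / (2 * sum_i p_i (1 - p_i)),   Z = X - 2p,

with allele frequencies estimated from the data.  Monomorphic markers are
dropped with a logged count.

**Target-gene kernel (G2).**  Allele calls at a small set of characterised
loci (vernalisation, photoperiod, dwarfing) are expanded into per-class
indicator columns on the homozygous-dosage scale — an inbred line carries 0
or 2 copies of its class — and the genome-wide formula above is applied
literally to that matrix.  This makes a biallelic gene reduce *exactly* to
the genome-wide kernel of its 0/2 recoding, which pins down the otherwise
open scaling choice.  A joint encoding over observed multi-gene allele
combinations is available (`joint=True`); the per-gene encoding is the
default.

`validate_kernel` enforces symmetry to 1e-10 and positive semi-definiteness
to -1e-8; a failing kernel receives the smallest diagonal jitter from
{1e-8, 1e-6, 1e-4} that repairs it, recorded on the object.

## Stage 3: Bayesian GBLUP family

Four model families are fitted by Gibbs sampling, all working in the
eigenbasis of G so no n x n solve appears inside the chain:

* **SE** — y = 1 mu + u + e, u ~ N(0, G sigma_g^2);
* **MT** — Y = 1 mu' + U + E, U ~ MN(0, G, Sigma_t), residual rows i.i.d.
  N(0, R) with unstructured R;
* **ME** — y_ij = alpha_i + L_j + g_j + Eg_ij + e_ij, with an i.i.d. line
  effect L (droppable via `include_line_effect=False`), genomic main effect
  g ~ N(0, G sigma_g^2) and interaction Eg whose Hadamard covariance
  (Z G Z') o (Z_E Z_E') sigma_Eg^2 makes it independent across environments
  with within-environment covariance G sigma_Eg^2;
* **MTME** — Y = X beta + Z1 b1 + Z2 b2 + E with b1 ~ MN(0, G, Sigma_t) and
  b2 ~ MN(0, Sigma_E (x) G, Sigma_t).  The fixed part is one mean per
  (environment, trait) cell, an equivalent reparameterisation of
  intercept-plus-environment-contrasts.  b2 is sampled in the joint
  eigenbasis of Sigma_E (re-decomposed each sweep; it is only m x m) and G
  (precomputed), so the update is a stack of independent t-dimensional
  normals and the Kronecker matrix is never formed.  Sigma_t is shared
  between b1 and b2, as the model is written; `separate_trait_cov=True`
  gives the interaction its own trait covariance.

**Missing cells** are handled by data augmentation: each unobserved cell is
drawn from its conditional normal given the observed traits of the same
line-by-environment cell (grouped by missingness pattern).  This is the
mechanism by which CV2 borrows secondary-trait and other-environment
information.

**Priors.**  Scalar variances: scaled-inverse-chi-square with 5 degrees of
freedom and scale set so the prior mode assigns half the phenotypic
variance to the component (for sigma_g^2 and sigma_e^2).  The ME model's
secondary components (sigma_Eg^2, sigma_L^2) get a lighter prior, mode at
5% of the phenotypic variance: the inverse-chi-square density vanishes at
zero and therefore floors any posterior near its own scale, and a truly
null interaction must be able to collapse below detection.  Covariances
(Sigma_t, Sigma_E, R): inverse-Wishart with df = dimension + 3 and scale
0.5 x diag of the phenotypic covariance; Sigma_E, which is a relative scale
across environments (Sigma_t carries the trait units), uses 0.5 I.

**Chains.**  Defaults: 12,000 iterations, 2,000 burn-in, thinning 5, all
configurable per `MCMCSettings`; a single integer seed makes every fit
reproducible.  Effective sample sizes of the variance components are
computed (arviz) and a warning is raised below 100.  `fix_variances` pins
named components — the degenerate-prior mode used for closed-form
cross-checks.

**Warm start.**  The scale split between the interaction effects and the
residual is only weakly identified when G is close to the identity, and a
chain started at b2 = 0 can stall in a collapsed-interaction mode.  The
MTME sampler therefore starts from a method-of-moments decomposition of the
centred data (line means for b1, half the leftover for b2) with Sigma_E at
the identity.

**Identifiability caveat.**  With an unrelated Hardy–Weinberg panel and
many markers, G ≈ I and the genetic/residual split is nearly unidentifiable
— a property of the model class, not of this implementation (an independent
closed-form ML oracle agrees with the samplers on such data).  Real
breeding panels carry strong relatedness structure; in the generator that
structure is controlled by the marker count, and the parameter-recovery
tests use n_markers ≈ 0.75 x n_lines to give the kernel a realistic
eigenvalue spread.  Relatedly, a compound-symmetric part of Sigma_E is
absorbed by b1/Sigma_t (the shared-across-environments component of the
interaction is indistinguishable from a main effect), so individual
components of the (Sigma_t, Sigma_E) product are reported as estimated but
only their product is sharply identified; the `genomic_heritability`
helper, Sigma_t_tt * mean diag G * (1 + mean diag Sigma_E) against R_tt,
is invariant to that trade-off.

## Stage 4: cross-validation

`make_folds` draws independent uniformly random k-fold partitions per cycle
(fold sizes differ by at most one, remainder assigned one per fold in
random order); defaults follow the 10-cycles-of-5-fold protocol.  CV1 hides
every cell of a test line within the model's scope; CV2 hides only the
target-trait cells in the target environments, keeping secondary-trait and
other-environment records observed.  Cells already missing stay missing and
are never scored; a fold that would leave a target environment with fewer
than two training lines is rejected.

Prediction ability is the Pearson correlation between predicted and
observed BLUEs of masked cells, computed per environment per cycle by
pooling the folds of that cycle (a per-fold variant is available via
`per_fold=True`), then summarised as mean and SD over cycles.  Constant
predictions or fewer than three scored cells yield a missing ability with a
warning; a failing fold is recorded as missing for its cycle rather than
aborting the run.  `rank_models` sorts by mean ability, breaking ties by
smaller SD then label, with labels following the
`<family>[_<scheme>][_G2]` grammar (SE carries no scheme suffix because
CV1 and CV2 coincide for its scope).

## Stage 5: SREG / GGE

For one trait's line x environment BLUE table, missing cells are first
completed by iterative rank-2 SVD approximation (column-mean start,
tolerance 1e-6, at most 500 iterations; rank 2 matches the two-component
biplot, and single-shot column-mean imputation remains available).  Each
environment column is then centred — removing the environment main effect
and leaving G+GE — and decomposed by SVD.  Genotype-focused scaling
(singular values on the genotype scores) is the default, symmetric scaling
a flag; signs are fixed so each component's largest-magnitude environment
loading is positive.  The headline quantity is
(lambda_1^2 + lambda_2^2) / sum lambda_k^2, the share of G+GE variation in
the biplot plane.

## The synthetic generator

`synth` emulates the study design: 186 lines, eight sowing-by-season
environments ("s_season" labels, 3+3+2 across three seasons), seven traits
(GN, GW, NS, SL, SW, HD, PH), two replicates with two incomplete blocks
each.  Genotypes are binomial Hardy–Weinberg draws with uniform allele
frequencies on [0.05, 0.5]; target genes are categorical draws from
declared allele frequencies whose per-allele trait effects (zero by
default, so the purely polygenic case is the base case) add to the genetic
values.  Genetic main effects are matrix-normal with row covariance G and
column covariance Sigma_t; interaction effects have row covariance
Sigma_E (x) G.  Default Sigma_t combines trait-scale SDs with a correlation
structure that is strongly positive among yield components (e.g. 0.95
between spike weight and grain weight) and weak toward phenology/height;
default Sigma_E correlates environments at 0.5 within a season and 0.25
across seasons on unit scale.  Residual plot variance is back-computed from
the per-trait entry-mean heritability target (defaults between 0.42 and
0.90, matching the moderate-yield/high-phenology pattern) via
sigma_e^2 = r * sigma_g_total^2 * (1 - h^2) / h^2; replicate and block
variances default to 5% of total genetic variance each.  All randomness
derives from one integer seed through named substreams, so each stage is
reproducible in isolation.

What the generator does *not* emulate: linkage disequilibrium, selection
or pedigree history, spatial field trends, weather-driven environmental
structure, or trait-correlated measurement error.  Passing tests therefore
establish internal statistical correctness (the samplers recover what the
generator injects, the schemes order as the borrowing structure predicts),
not performance on any real panel.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` run scaled versions of the
design chosen for tractable single-CPU runtimes: parameter recovery at 200
lines x 4 environments x 3 traits with the default 12,000-iteration chain;
scheme-ordering CV at 120 lines, 2 environments, 2 traits (trait
correlation 0.8, h^2 = 0.5) with 800-iteration chains — posterior-mean
predictions stabilise long before the variance components do; the
acceptance script at 150 lines, 4 environments, 4 traits, 3 CV cycles.  In
the acceptance run the phenology genes carry effects of realistic magnitude
(about 1–1.5 phenotypic SD of heading date between extreme allele classes),
so the target-gene kernel is informative for HD and near-null for yield
components, mirroring the intended use of functional-allele data.

## Known limitations

* Residual covariance in MT/MTME is one unstructured trait x trait matrix
  shared across environments; heterogeneous-by-environment residuals are
  out of scope.
* Marker-effect models (Bayes A/B/C), dominance/epistatic kernels and
  spatial adjustment are out of scope.
* The BLUE standard errors from stage 1 are reported but not propagated
  into the stage-2 models (each cell enters unweighted, as in the two-stage
  convention the models follow).
* Permutation equivariance of the samplers holds up to Monte-Carlo error
  only: permuting line order permutes the kernel eigenbasis and therefore
  re-maps the random-number stream.
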