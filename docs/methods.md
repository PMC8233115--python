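# Methods

## The model

One Bayesian hierarchical regression is fitted per cognitive outcome. The
outcome vector is z-scored over the per-outcome complete cases (rows with a
missing outcome are dropped; no imputation). Predictors are the 2k slotted
atom loadings — k atoms for the left hemisphere, k for the right, with the
off-hemisphere block exactly zero for every unilateral patient — plus the
covariate block. The generative structure:

- τ ~ HalfNormal(s_τ): joint hyperprior tying both hemispheres together.
- σ_h ~ HalfNormal(τ) for h ∈ {L, R}: one dispersion per hemisphere,
  governing *all* of that hemisphere's atom coefficients. The posterior of
  (σ_L, σ_R) is the hemisphere-level relevance statement: a hemisphere whose
  atoms collectively predict the outcome forces its dispersion away from
  zero, in analogy to a variance component in ANOVA.
- β_{h,a} ~ Normal(0, σ_h²): per-atom coefficients.
- γ_j ~ Normal(0, 1), α ~ Normal(0, 1), σ_ε ~ HalfNormal(1).
- y_i ~ Normal(α + Σ β_{h,a} H_{i,h,a} + x_iᵀγ, σ_ε²).

Prior families are weakly informative half-normals and unit normals; all
scales (`hyperprior_scale`, default 0.5; `covariate_prior_sd`,
`noise_prior_scale`, default 1.0) are configuration-exposed so alternative
families or scales can be swapped in. Because outcomes are z-scored, the
intercept posterior concentrates near zero but is kept in the model.

Parameterization: both hierarchy levels are non-centred — β = σ_h·b with
b ~ N(0,1), and σ_h = τ·e_h with e_h ~ HalfNormal(1) — and positive scales
are sampled on the log scale with the Jacobian term. This removes the
funnel geometries that otherwise produce divergent transitions.

## Sampling

Posterior draws come from a No-U-Turn sampler written for this model:
multinomial NUTS with biased progressive sampling over the doubling
trajectory, dual-averaging step-size adaptation (target acceptance 0.9),
Stan-style expanding windows estimating a diagonal mass matrix, and a
divergence threshold of 1000 on the energy error. Defaults: 3500 draws,
1000 tuning iterations, 4 chains, maximum tree depth 10. Two
implementations exist: a readable pure-python engine (`lesionatoms.nuts`)
and a numba-compiled kernel (`lesionatoms._kernel`) with the identical
algorithm and an identical log-density (agreement is asserted to machine
precision in the tests, and the two engines' posterior means are
cross-checked on a shared cohort). Runs with split-R̂ > 1.01 or more than
0.1% divergent transitions are *flagged* non-converged in the diagnostics
rather than raised as errors, so sensitivity reruns always complete and can
be inspected.

Scale-clamped model variants (τ, σ_L, σ_R, σ_ε fixed; used for the ridge
closed-form check) have an exactly Gaussian posterior whose strongest
structure is linear correlation between the intercept and the non-centred
loading block; these are routed through the python engine with a *dense*
mass matrix, which samples them nearly independently. The hierarchical
(non-Gaussian) model keeps the diagonal metric: empirically the dense
covariance estimate is noisier than its benefit there.

## Atom decomposition

NMF minimizes the squared Frobenius reconstruction error by coordinate
descent (scikit-learn backend behind the module surface). The default
"pooled" mode stacks every patient's lesioned-hemisphere 54-region
log-load vector into one sample pool and fits a single shared basis: left
and right atoms are then homologous by construction, which is what the
atom-level left-minus-right contrasts require. A "concatenated" mode
(k atoms on the full 108-dimensional space) is available behind a config
switch. Five restarts by default — the first uses the deterministic nndsvda
initialization, the rest seeded random initializations — keeping the best
objective. Conventions: W columns are L2-normalized with the scale pushed
into H (so atom coefficients are comparable across atoms); atoms are
ordered by descending W-column L1 mass with ties broken by the lowest
dominant-region index; loadings are standardized by the pooled standard
deviation of the nonzero slotted entries before entering the regression
(config-exposed). Lesion loads are transformed with log1p rather than log
because zero loads are the norm.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes:

- **Basis**: each of k = 10 atoms gets a contiguous block of 3–8
  high-weight regions anchored in its own stretch of the 54-region axis,
  plus a tiny uniform background (no region has weight exactly zero). When
  regions are too few for 3-wide blocks the atoms fall back to disjoint
  one-segment blocks.
- **Lesions**: hemisphere ~ Bernoulli(prob_left = 0.5); atom loadings
  Gamma(shape 2, mean `loading_scale` = 30) for the lesioned hemisphere,
  zero for the other; region loads = round(exp(ε)·(W·h)) with multiplicative
  log-normal noise of sd `load_noise_sd` = 0.05, rounded to integer voxel
  counts. The gamma loading distribution is a stand-in chosen for
  non-negativity and right skew; no empirical loading distribution informs
  it.
- **Covariates**: age (mean 67, sd 11 years), binary sex, days since
  stroke, education years, IQCODE, and the realized total lesion volume;
  continuous columns are z-scored with the population (divide-by-n)
  standard deviation, and age² / age×sex are built from z-scored age and
  then z-scored themselves.
- **Outcomes**: β_{h,a} ~ N(0, σ_h²) with σ_true = (0.30, 0.03) by default
  (a strongly left-dominant truth); y = α + H_std β + Xγ + N(0, noise_sd²).
  When `noise_sd` is unset it is calibrated from the realized signal
  variance so the generative R² equals `target_r2` = 0.5. Setting
  `mirror_beta` makes homologous atoms share one coefficient draw — a true
  atom-level null used for lateralization-flag calibration. Default
  covariate effects (z-scale): education +0.06, IQCODE −0.35, lesion volume
  −0.21, age −0.10, small or zero for the rest.
- **Voxel masks**: a toy atlas of 6×6×6-voxel cubes per region, mirrored
  across hemispheres, lets the mask→counts parcellation be exercised end to
  end; voxels are painted deterministically so the round trip is exact.

What the generator does *not* emulate: vascular-territory geometry,
spatially correlated segmentation error, registration artefacts, missing
covariates, or floor/ceiling effects in test scores. Passing tests
demonstrate the statistical machinery is correct and calibrated under the
assumed data-generating process — not that real lesion data satisfy those
assumptions.

## Relevance summaries

All intervals are highest-posterior-density intervals computed on the
chains pooled after the convergence check: the narrowest window over the
sorted draws containing ⌈prob·n⌉ draws (prob = 0.94), ties resolved toward
the lowest lower bound; an exhaustive window search serves as the test
oracle. The atom-level difference is oriented left minus right (negative =
left-lateralized predictive relevance of lost function), recorded in every
output row; no multiplicity correction is applied across the 10 atom
contrasts (a config flag can widen intervals). Region relevance is the
per-draw back-projection W·β_h, summarized per region × hemisphere; the
loading scale is deliberately not folded in. Bayesian R² per draw is
Var(fitted)/(Var(fitted) + σ_ε²) with the model-based residual variance.
Hemisphere "dominance" labels are descriptive (larger posterior mean),
never a test.

## Problem sizes in the test-bed

The repeated-simulation batteries run at: dispersion recovery and R²
recovery — 20 cohorts of n = 600, k = 10, fits at 4 chains × 1000 draws
(800 tuning); null-calibration — same sizes with mirrored coefficients;
ridge check — one n = 600 clamped fit; HPDI oracle — 1000 random vectors;
NMF battery — 20 cohorts of n = 600; parcellation round trip — 50
patients; covariate coverage — 50 correctly specified fits at n = 300,
k = 4, 2 chains × 500 draws. These sizes were chosen so each battery gives
stable pass/fail behaviour at desk scale.

## Known limitations

- The per-hemisphere dispersion posterior shrinks toward zero at small n or
  weak signal; with k = 10 atoms its posterior mean underestimates a true
  σ = 0.30 noticeably (hierarchical shrinkage), which is why recovery is
  asserted as an ordering (σ̂_L > σ̂_R), not as a point match.
- The NMF basis is identified only up to atom permutation (handled by the
  deterministic ordering) and is a local optimum; restarts mitigate but do
  not guarantee the global one.
- The lateralization flag inherits the usual caveats of interval-null
  testing: under hierarchical shrinkage it is conservative (fires less
  often than the nominal 6% under a true null).
- Masks must already be on the atlas grid; the package refuses to resample.
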