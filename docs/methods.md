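# Methods

This note documents the statistical procedures `endotrend` implements,
the defaults it ships with, and the choices made where the design was
genuinely open. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Record filtering

Museum record sets are opportunistic samples, so three filters precede
any trend estimation:

1. **Inclusion** — keep species with *more than* `min_records` (default
   100) complete records whose collection years span at least
   `min_span_decades × 10` years (default 40). The span rule is
   length-based (`last_year − first_year ≥ 40`); a calendar-anchored
   alternative ("must cover the most recent four decades") can be
   emulated by pre-filtering on `last_year`.
2. **Concentration** — drop species for which any `window`-year sliding
   window (default 10, anchored at each observed collection year)
   contains more than `frac` (default 80%) of the records. A series like
   that supports a between-era contrast, not a trend.
3. **Mass outliers** — drop non-positive masses and masses at or below
   `rel_threshold` (default 1%) of the species median. "Close to zero"
   has no absolute meaning across species spanning five orders of
   magnitude of body mass, so the rule is relative; the threshold is
   configurable.

The chain is idempotent and order-stable; every removal is counted in a
`FilterReport`. Filter order (inclusion → concentration → outliers)
affects only the attribution of removals, not the surviving set in any
case exercised by the tests.

## Per-species trend statistic

Within a species, mass is regressed by OLS on year, |latitude|,
longitude and a male indicator (female is the reference level; longitude
enters signed, latitude as absolute value because the covariate of
interest is distance from the equator, not hemisphere). The trend
statistic is the partial correlation

r_year = t / √(t² + ν),

with t the year coefficient's t-statistic and ν the residual degrees of
freedom. This equals the correlation of the residuals of mass and year
after each is regressed on the remaining covariates; the test suite
checks that identity to 1e−10 on random data, and with no usable
covariates r_year reduces to the plain Pearson correlation. Covariate
columns that are constant within a species (single-sex series, single
collection site) are dropped with a warning and recorded. Significance
is two-sided at α = 0.05 per species, uncorrected: the classification
(increase / none / decrease, strict `p < α`) mirrors how such per-species
summaries are conventionally reported, and the downstream analyses use
the continuous r_year, not the classification.

## Cross-species comparison

`r_year` values are compared across species with a full-factorial 2×2
model (class, habitat, class×habitat) using Type III sums of squares
under sum-to-zero coding — the appropriate choice for this heavily
unbalanced design (default synthetic cells 10/17/4/13). With n species
the residual df is n−4 (40 at n=44), and the ANCOVA adding time-series
length as a covariate has n−5 (39). The ANCOVA also reports a
parallelism (homogeneity-of-slopes) test: a joint F-test of the
factor×covariate interactions against the additive model. Assumption
checks are the one-sample Kolmogorov–Smirnov test against a normal with
estimated mean/sd (no Lilliefors correction) and Levene's test on
absolute deviations from group means; both are reported for model
residuals, and the raw r_year values can be passed instead. All F values
are validated against a brute-force residual-sum-of-squares
model-comparison oracle in the tests.

## Phylogenetic mixed model

Each individual record is one observation. The model for standardized
mass z is

z_ij = x_ij'β + u_s(i) + e_ij, u ~ N(0, σ_a²A), e_ij ~ N(0, σ_e²).

* **Relatedness matrix A.** A[i,j] is the branch length shared by the
  root-to-tip paths of species i and j (the depth of their most recent
  common ancestor); missing branch lengths default to 1, making entries
  shared-branch counts. The default scaling divides by
  √(A[i,i]·A[j,j]) so the diagonal is 1 and σ_a² is comparable across
  trees; the raw matrix is available. If A fails a Cholesky
  factorization, 1e−8 is added to the diagonal once; failure after that
  is fatal.
* **Standardization.** Default scope is within-species z-scores (sample
  sd): it removes the allometric spread so all terms act on relative
  size. Note the consequence: any purely species-level constant (the
  species' own mean, and with it most of the marginal phylogenetic
  signal in *level*) is removed from the response, so σ_a² mainly
  absorbs species-level offsets left by the covariates, and class/habitat
  *main* effects are weakly identified — their interactions with year
  are the estimable quantities of interest. A pooled `global` scope and
  `none` (use mass as-is) are available.
* **Fixed effects.** Model A: intercept, year (raw calendar year),
  class(mammal), habitat(terrestrial), |latitude|, longitude, sex(male),
  series length. Model B adds year×class; model C adds year×habitat.
  The "period" variant — used for the before/after-1950 fits — has only
  year, |latitude|, longitude and sex. Reference levels (bird, aquatic,
  female) fold into the intercept. Year enters uncentered so intercepts
  are on the calendar scale; `center_year=True` centers internally for
  conditioning and transforms every affected coefficient of every
  retained draw back to the raw scale.
* **Priors.** Independent N(0, 1e8) on each fixed effect (effectively
  flat). Both variances get the univariate inverse-Wishart — an
  inverse-gamma with shape ν/2 and scale νV/2 — with ν = 3 and
  V = var(z)/2 by default; both are configurable, and σ_a² can be pinned
  to a constant (`fixed_phylo_variance`), which reduces the model to
  ordinary regression and is used as a sampler cross-check against OLS.
* **Sampler.** Blocked conjugate Gibbs: the stacked (β, u) vector is
  drawn jointly from its Gaussian full conditional via the mixed-model
  equations (one Cholesky of a (p+q)×(p+q) matrix per iteration;
  cross-products precomputed once), then σ_a² and σ_e² from their
  inverse-gamma full conditionals. Joint blocking removes the dominant
  β–u autocorrelation, so short thinning intervals already give nearly
  independent draws. Chains are bit-reproducible given the seed.
* **Chain defaults.** 250,000 iterations, 50,000 burn-in, thinning 100 →
  2,000 retained draws. The pMCMC floor is therefore 1/2,000 = 5.0e−4.
* **Summaries.** Posterior mean, equal-tailed 95% credible interval,
  pMCMC = max(1/n, 2·min(#pos, #neg)/n) per coefficient (undefined and
  flagged if every draw is exactly zero), effective sample size on
  request (via arviz). DIC is computed conditional on the species
  effects (random effects in focus): D̄ + p_D with
  p_D = D̄ − D(θ̄, σ̄_e²).

## Period contrast

Records are split at the boundary year (1950; the boundary year itself
belongs to the first period). Per-period trends feed a classical paired
t-test across species present in both periods, and per-period PGLMMs
("period" fixed-effect set, same priors and chain settings) feed the
posterior contrast: iteration-by-iteration differences of each
coefficient's retained draws (after minus before), summarized exactly
like a coefficient (mean, 95% interval, pMCMC). Both chains must retain
the same number of draws; pairing by iteration index is valid because
the two chains are independent, so the difference distribution is the
distribution of the difference of two independent posterior draws.

## Synthetic-data generator

`SimConfig` defaults define the study conditions the package is tested
under, chosen to mirror the real design: 44 species in class-habitat
cells 10/17/4/13 (aquatic birds / terrestrial birds / aquatic mammals /
terrestrial mammals); per-species first collection year uniform in
1915–1960 and last year 2013 (so series lengths vary, as in real
collections); 150–600 records per species; aquatic trend +0.003
sd/year throughout; terrestrial trend 0 before 1950 and −0.006 sd/year
after (a hinge, continuous at the boundary); |latitude| effect 0.011
and male effect 0.046 sd; σ_a² = 0.2, σ_e² = 1; species mean masses
log-uniform on 5 g – 500 kg, mapped to grams by
mass = mean·(1 + 0.1·z). Sampling over years is uniform by default with
an optional era-biased mode (linearly increasing sampling intensity).
Species intercepts are drawn from N(0, σ_a²A) on the same tree used for
fitting; the realized effects and every parameter are written to a
ground-truth JSON.

What the generator does **not** emulate: age structure, seasonality,
measurement-protocol drift, spatially structured sampling, and
non-Gaussian mass distributions. Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed model, not
robustness of the scientific conclusions to those real-data
complications.

## Problem sizes and numerical choices

The unit tests run the sampler with shortened chains that keep the
2,000-retained-draw convention (e.g. 25,000/5,000/10) — with joint
blocking the retained draws are nearly independent either way — while
`scripts/acceptance.py` uses the full 250,000-iteration default.
Parameter-recovery checks use 20 species × 100 records over 20 fixed
seeds and require ≥ 90% coverage of the generating year slope and
year×habitat interaction by the 95% credible intervals. Degenerate
inputs are handled explicitly: zero-variance species are fatal for
standardization, constant design columns are dropped with a warning,
zero-variance paired differences are flagged rather than tested, and
constant covariates in correlation tables are flagged as such.

## Known limitations

* Gaussian response only; one random effect (species); no missing
  branch-length estimation beyond the unit default.
* The within-species standardization scope and the exact composition of
  the per-period fixed effects are documented choices, not identities;
  both are configurable where the original analysis left them ambiguous.
* DIC for hierarchical models depends on the focus; the conditional
  (species-effects-in-focus) deviance used here is the convention of the
  animal-model literature but is not comparable to marginal DIC values.
* The concentration filter's sliding window is anchored at observed
  years; window placement conventions differ across implementations and
  can flip borderline species.
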