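# Methods

This note documents the statistical machinery, the defaults and the design
choices made where the design was genuinely open. Everything quantitative
stated here is computed by the test suite or the acceptance script.

## Pedigree algebra

The numerator relationship matrix **A** is built by the tabular method in
topological order: `a_ii = 1 + ½·a_{sire,dam}` and
`a_ij = ½(a_{j,sire(i)} + a_{j,dam(i)})`, with unknown parents contributing
zero. Unknown parents are treated as unrelated founders drawn from the base
population — the standard animal-model convention. Inbreeding is
`F_i = a_ii − 1`, computed by memoised recursive kinship so that the full
matrix is not needed. A is stored dense up to 5,000 individuals and in
sparse (CSR) storage above, with identical values either way; at the desk
scales this package targets the dense path is the one exercised.

Pedigree depth counts founders as generation 1 (a parent–offspring pair has
depth 2). Topological sorting is Kahn's algorithm with stable tie-breaking
by input order, so all outputs are reproducible. Trimming keeps phenotyped
individuals and their ancestor closure, exactly: collateral relatives with
no phenotyped descendants are removed.

## The animal model

Records are modelled as `y = Xb + Z_a a + Z_pe p + Z_t t + e` with
`a ~ N(0, A·V_A)`. The breeding-value vector spans the whole (trimmed)
pedigree, so predictions for unphenotyped ancestors come out of the same
equations. Fixed designs use reference-level coding with the alphabetically
first level as reference; continuous covariates are centred and scaled to
unit variance before quadratics and interactions are formed (the centring
constants are carried in the design labels). Year is centred at the sample
mean, recorded in the design transforms. In Model B, year enters both as a
factor (detrending the phenotype) and as a centred continuous covariate
inside its interactions with distance; the continuous main effect is
excluded to avoid collinearity with the year factor. Collinear columns are
removed by pivoted QR and logged.

### REML

Variance components maximise the restricted likelihood via EM steps on the
mixed-model equations (built with full **A**, numerically inverted), with
Aitken acceleration on the log-variance vector every fourth iteration. Each
accelerated step is accepted only if it increases the restricted
log-likelihood, which makes large extrapolations safe: the V_A/V_PE ridge
common in repeated-records data has EM convergence rates around 0.999, so
the rate clip for acceleration is set at 0.9999. Convergence is declared at
a relative log-likelihood change below 1e-8 or a maximum absolute
log-variance step below 1e-7; components falling under `1e-10·V_P` are
pinned at that bound and flagged. The restricted log-likelihood is evaluated
through the standard determinant identity
`log|V| + log|X'V⁻¹X| = log|R| + log|G| + log|C|` (C the MME coefficient
matrix); the identity is verified against a direct dense-V evaluation in the
tests, and the EM fixed point against a derivative-free direct maximiser.

Standard errors come from a central-finite-difference observed information
matrix at the optimum, with delta-method SEs for h² and repeatability; they
are labelled as such and suppressed for boundary-pinned components.

### Gibbs sampler

The sampler updates whole blocks from their exact full conditionals: fixed
effects (multivariate normal, using a pre-factorised X'X), breeding values,
permanent-environment and trainer vectors, then each variance from its
scaled inverse-chi-square conditional. Priors are univariate inverse-Wishart
in the MCMCglmm parameterisation (nu = 0.002, V = 1), i.e. essentially flat.

Breeding values are updated through a whitening rotation: with `A = LL'` and
`M = L'DL = U·diag(λ)·U'` (D the per-individual record counts), the rotated
vector `v = U'L⁻¹a` has prior `N(0, V_A·I)` and diagonal data precision
`λ/V_R`, so a sweep costs two dense matrix–vector products instead of a
Cholesky factorisation. Above 1,000 pedigree individuals the rotation
matrices are held in single precision; the induced perturbation is orders of
magnitude below the Monte-Carlo noise. Chains are fully reproducible from a
single root seed, and retained draws number `(n_iter − burn_in) // thin`.

The bivariate model shares one pedigree and gives the two traits a full 2×2
additive covariance matrix, updated from its inverse-Wishart full
conditional (df = nu + q with nu = 0.004, scale nu·I). Each trait's
breeding values are drawn conditionally on the other's using the whitened
update with a conditional prior mean `(g_12/g_22)·w_other`. Permanent
environment and trainer effects are kept uncorrelated across traits, and
the residual covariance between traits is fixed at zero: the two traits are
measured in different races, which are distinct events. The genetic
correlation is summarised by its kernel-density posterior mode and a 95%
equal-tailed credible interval (more stable than an empirical HDI at this
chain's effective sample size). Fitting requires cross-classified individuals or
pedigree links between the trait sets; otherwise r_G is unidentifiable and
the fit refuses to run.

### Diagnostics

Stationarity uses the Heidelberger–Welch procedure: a Cramér–von Mises
statistic on the Brownian bridge of the chain, normalised by the spectral
density at zero (an AIC-selected autoregressive fit to the second half of
the chain), discarding the initial 10%, 20%, … 50% until the remainder
passes at α = 0.05. The asymptotic CvM distribution function uses the
classical Bessel-K series. Lag-1 autocorrelation of the retained draws is
reported with a pass flag at |ρ₁| < 0.1; a constant chain has undefined
autocorrelation (reported as NaN) and passes stationarity trivially.

## Genetic trend and the drift test

β_G is the unweighted OLS slope of cohort-mean predicted breeding value on
year of birth; cohorts default to phenotyped individuals, matching the data
subsets the model was fitted to (weighting by cohort size is available as
an option). With posterior breeding-value draws the regression is repeated
per draw; the point estimate is the KDE mode (Gaussian kernel, Silverman
bandwidth), the interval a 95% HDI, and `p_positive` the posterior mass
above zero.

The drift test gene-drops neutral breeding values down the observed
pedigree: founders `~ N(0, V_A)`, offspring take the parental mean plus a
Mendelian deviation of variance `½·V_A·(1 − (F_s + F_d)/2)`; an individual
with one known parent takes half that parent's value plus a deviation of
variance `¾·V_A` (the unknown parent's founder draw folded in). The
parental-inbreeding correction is included because omitting it overstates
drift variance in inbred pedigrees. Each of `n_sim` replicates draws one
V_A value from the posterior (with replacement), simulates, and computes
the cohort slope over the same window and cohort definition as the observed
β_G. By default each drift slope is compared against an independent
with-replacement draw from the β_G posterior ("resample" pairing); the
alternative of comparing every posterior draw against every drift slope is
available and agrees in expectation. Selection is declared at
`P(β_G > drift) > 0.95`.

A property worth knowing when interpreting results at small scale: cohort
means of *predicted* breeding values are shrunken towards zero relative to
the true genetic trend, increasingly so as per-horse information falls, and
in Model A part of a genuine trend is absorbed by the race-identity factor.
The drift test remains calibrated under the null (the posterior and the
null are computed from the same machinery), but its power at desk scale
requires wide cohorts — see "Problem sizes" below.

## Selection intensity

`i = β_G·L / (h·σ_A·√(n/(1 + (n−1)R)))` with L the mean parental age at
offspring birth (sire and dam pairs pooled jointly), n the mean record
count per horse treated as a scalar, and R the repeatability. The implied
selected proportion solves `i = φ(Φ⁻¹(1−p))/p` by Brent root-finding on
(1e-8, 1−1e-8) to 1e-10 in p, with the closed-form inverse available in the
other direction. Intensities outside the numerically attainable range raise
an error naming the bound.

## The synthetic-data generator

The generator emulates the structure the models assume, not race dynamics:
overlapping generations with a configurable sire pool (a small pool creates
the very large paternal half-sibships characteristic of thoroughbred
pedigrees), one foal per dam per year, parental ages drawn around a mean of
9.5 years, repeated records per horse across ages 2–12, races with
distance, going, field size, racecourse and timing-method covariates, and
speed assembled as mean + fixed effects + BV + permanent environment +
trainer + residual. True breeding values follow exactly the gene-drop
transmission rule, so the generator and the drift null are mutually
consistent by construction. Selection, when active, is truncation on true
breeding value of the sire pool — chosen over phenotypic truncation for a
clean link to the selection-intensity arithmetic. Trainer allocation can be
correlated with sire breeding-value rank to reproduce the "better-bred
horses go to better trainers" confounding.

Default variances are V_A = 0.0397, V_PE = 0.0723, V_T = 0.032,
V_R = 0.176: V_P = 0.32 so that h² = 0.124, repeatability 0.35 and a
trainer share of 10%, around a mean speed of 18 yards/s — sprint-race study
conditions with σ_A = 0.2. A bivariate helper gene-drops two correlated
traits (founder and Mendelian covariance `r_G·σ_A1·σ_A2`) for genetic-
correlation experiments.

What the generator does *not* emulate: non-normal residuals, heterogeneous
residual variances across going or distance, running-line and draw effects,
jockey effects, maternal effects, and selective starting (horses chosen to
race based on early performance). Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to these real-data features.

## Problem sizes

All tests run at desk scale, chosen as the smallest sizes at which each
property is informative: parameter recovery uses ~770 phenotyped horses
with ~5.7 records each (REML SE on h² ≈ 0.036); the drift-test power
experiment uses 14 cohorts of 150 foals under strong sire selection (top
3%), where the realised trend is several drift SDs and detection is
essentially certain; its type-I calibration uses 14 cohorts of 60 foals.
Bivariate coverage runs on founder-rich pedigrees (150 founders, ~360
individuals) so the realised genetic correlation stays near the generating
parameter, with 6,000-sweep chains — the genetic correlation mixes slowly,
and shorter chains understate the posterior spread. The balanced half-sib
cross-check uses 100 sires × 20 offspring, where the animal-model h² and
the ANOVA sire-model estimator agree to numerical precision.

The null-heritability check deserves a note: the sampling SD of ĥ² under
V_A = 0 is about 0.012–0.015 at up to ~1,000 horses (profile likelihoods
confirm the occasional ĥ² ≈ 0.03 fit is a true restricted-likelihood
maximum, not an optimiser artefact), and only falls to ~0.01 near 3,000
horses. The test therefore asserts that each replicate's estimate is
consistent with zero — below 0.02, or within two of its own standard
errors when the desk-scale sampling error exceeds that bound.

## Known limitations

- REML uses dense mixed-model equations with full A: memory and time grow
  cubically, and pedigrees beyond a few thousand individuals are out of
  scope (A⁻¹ sparse machinery is deliberately not implemented).
- Standard errors are observed-information delta-method approximations and
  are unreliable when a component sits on the boundary.
- The trivariate genetic-correlation analysis is replaced by bivariate
  fits per trait pair; likelihood-ratio tests of r_G = +1 are not provided
  (credible intervals serve that role).
- β_P, the phenotypic trend used in the β_G/β_P ratio, is user-supplied
  input, not estimated here.
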