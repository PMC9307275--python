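# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `climpop`.

## Scope and data flow

The package estimates, in two stages, how annual weather anomalies relate to
annual population growth rates across many abundance records, and whether
species life history predicts the absolute size of those responses.

1. monthly weather per record → z-score → STL → annual anomaly `W_t`
   (and annual within-year variance of the raw monthly values);
2. abundance record → inclusion filters → growth rates `r_t` →
   penalized-spline AR(1) regression → per-record coefficient ω with SE;
3. record-level ω across species → Gaussian (directional) and Gamma
   (magnitude, log link) phylogenetic meta-regressions.

Raster extraction, taxonomy reconciliation beyond an explicit synonym map,
and matrix-population-model trait derivation are out of scope; the module
contracts start at a monthly weather series per record, a species-level
trait table, and a newick tree.

## Record inclusion rules

Records are clipped to the weather window (default 1979–2013).  Each maximal
run of consecutive years with at least `min_years` (default 10; 5 and 20
supported for sensitivity analyses) becomes its own record ("block
splitting"); shorter runs are dropped and logged.  A record is removed when
more than 32% of its abundances are zero AND at least one adjacent pair of
zeros occurs; the rule is a conjunction by default (a disjunction mode
exists), and records that exceed the proportion without adjacent zeros are
kept but QC-flagged.  Growth rates use the forward convention
`r_t = ln((X_{t+1}+1)/(X_t+1))`, pairing `r_t` with the weather of year `t`;
a backward labeling is available.  The +1 transform keeps zeros
representable at the cost of exact scale invariance; for abundances ≥ 1000
the distortion of `r_t` is below 0.002.

## Weather anomalies

Each record's monthly series is z-scored over the full window and decomposed
with STL at period 12, seasonal window 7 and trend window 1001.  The trend
window is the closest odd value to 1000 (loess windows are conventionally
odd); at ~420 monthly observations it makes the trend component very smooth,
effectively a multi-decadal baseline.  STL inner/outer iterations follow the
reference defaults (2 inner, 0 robustness) and are configurable.  The annual
anomaly is the mean of the 12 monthly remainders; the annual variance is the
sample variance of the 12 raw monthly values.  Partial years at the window
edges are dropped from annual summaries (with a warning), not imputed.
Because anomalies are computed from a z-scored series, they are invariant to
positive rescaling of the raw input, and ω is expressed per standardized
anomaly unit (no back-transformation to °C or mm).

## Stage-1 estimator

`WeatherGAMM` fits `r_t = β₀ + ω W_t + f(year_t) + ε_t` with AR(1) errors.
The smooth `f` uses a low-rank thin-plate-type basis: the radial basis
`|x_i − x_j|³` is projected off the polynomial null space {1, x}, its top
k−2 eigenvectors are retained (k = basis dimension, default 5), and the
linear year term is carried as an unpenalized column.  For fixed (λ, ρ) the
model is whitened by the AR(1) innovations transform and solved in penalized
least squares; λ and ρ maximize the REML criterion, with ρ profiled on a
grid (−0.9…0.9 step 0.1) and refined by golden-section search, and λ by
golden-section on log λ ∈ [−8, 12].  Standard errors use the Bayesian
posterior covariance σ̂²(CᵀC + S)⁻¹; `edf_trend_` reports the effective
degrees of freedom of the penalized smooth columns only (the unpenalized
linear year term, always ~1 edf, is reported separately), so a record with
no curvature shows `edf_trend ≈ 0`.  On identical data the estimator agrees
with `mgcv::gamm` + `corAR1` to ~0.01 on ω and ~0.003 on its SE (this
cross-check runs in the test suite via Rscript).

Calibration, measured by the test suite at T=30, ω=1, AR(1) noise sd 0.2,
ρ=0.3: mean ω̂ within 0.01 of truth and 95%-CI coverage ≈ 89–95%.

**Density dependence.** With a mean-reverting (Gompertz-type) pullback in
the generator, the weather signal accumulates in abundance and feeds the
mean-reversion term, so the covariate is no longer strictly exogenous; under
AR(1) whitening this inflates ω̂ by roughly ρ·dd (≈ +0.12 at dd = 0.3,
≈ +0.21 at dd = 0.5, identically in `mgcv::gamm`).  The estimator therefore
does not spuriously zero out or reverse weather effects under density
dependence — the qualitative robustness that matters for the framework —
but it is not unbiased at strong density dependence, and the package makes
no stronger claim.

**Alternative estimators.** `WeatherLinearModel` replaces the smooth with a
linear year term (same REML/AR(1) machinery).  `StateSpaceWeatherModel`
treats latent log(abundance+1) as a random walk with a linear weather effect
and process noise plus observation noise; the latent path is marginalized
exactly with a Kalman filter, so only (ω, log σ_process, log σ_obs) are
sampled, with `emcee` (16 walkers, 1200 steps, half discarded; split-R-hat
over walker sub-chains < 1.05 declares convergence).  Fit-to-sample
correlations use Rauch–Tung–Striebel smoothed states.

## Meta-regressions

Both models share the hierarchical structure: global intercept ᾱ, a
non-phylogenetic species intercept `a_SPECIES ~ N(0, σ²_SPECIES)`, a
phylogenetic species effect `g_PHYLO ~ MVN(0, σ²_PHYLO·V)` (V = Brownian
correlation, shared root-to-MRCA path length over tree depth), a z-scored
record-length slope β_N, and — Gaussian model only — biome effects in
treatment coding with the most frequent biome as reference.  The Gaussian
model adds a residual scale σ_resid (a Gaussian response model requires one
even though the printed hierarchical form leaves it implicit) with an
Exponential(8) prior.  The Gamma model uses the shape–mean parameterization
`|ω| ~ Gamma(η, rate = η/μ)` with `log μ` linear in the covariates; zero
magnitudes are floored at 1e-8 after z-scoring.

Priors (rate parameterization; Exponential(8) has mean 1/8):
ᾱ, β_BIOME ~ Normal(0, 0.3); β_N ~ Normal(0, 0.5) (Gaussian) /
Normal(0, 0.2) (Gamma); β_LH ~ Normal(0, 0.2) (0.3 is available in config —
both values appear in the source material's description of its priors);
σ²_PHYLO ~ Exponential(8) (Gaussian) / Exponential(11) (Gamma);
σ²_SPECIES ~ Exponential(8); η ~ Gamma(2, 0.6).  `prior_predictive`
simulates responses from the priors alone and checks that the central 95%
of draws stays inside the observed data range (default ±4 on the z scale).

**Sampling.** Posteriors are drawn by a static Hamiltonian Monte Carlo
sampler written for this package (`climpop.hmc`): analytic gradients,
non-centered random effects via the Cholesky factor of V (diagonal jitter
1e-10), variance parameters sampled on the log scale with Jacobian terms,
dual-averaging step-size adaptation to acceptance 0.9, diagonal mass-matrix
estimation over expanding warmup windows, and jittered trajectory lengths
(target length 2.0, at most 64 leapfrog steps).  Desk-scale default is 3
chains × 2000 iterations (1000 warmup); recovery studies in the tests and
the acceptance script use 3 × 800 (400 warmup), which keeps each fit at a
few seconds while leaving split-R-hat ≈ 1.01–1.07.  Measurement error in ω
(its stage-1 SE) is not propagated into stage 2, matching the printed
models; a measurement-error variant is a possible extension, not implemented.

**Model selection.** The default candidate set has 10 Gamma models: base
(record length only), three univariate life-history models, three
pairwise-additive, the full additive model, longevity×litter with its
interaction, and the full additive model with all 2-way interactions.  The
exact composition beyond "univariate, multivariate, 2-way interaction" is a
package choice and fully configurable.  Comparison uses PSIS-LOO pointwise
values (arviz); Δelpd is reported against the base model with the paired SE
of the pointwise differences.  Pareto-k diagnostics are recorded; with
per-species random effects conditioned on (rather than marginalized),
occasional k > 0.7 values are expected and reported, not hidden.

**Spatial check.** Moran's I uses inverse great-circle-distance weights
(zero self-weight) and a seeded permutation test (default 999 permutations,
one-sided for positive autocorrelation); the null expectation is −1/(n−1).

**Marginal predictions.** For a fitted Gamma model, the mean |ω| curve along
one z-scored trait uses the exact log-normal correction
`E[|ω| | z] = exp(ᾱ + βz + (σ²_PHYLO + σ²_SPECIES)/2)` averaged over
posterior draws; 80% prediction intervals come from posterior-predictive
draws with the varying effects integrated over their population
distributions.  A slope β across Δz trait units implies an `exp(β·Δz)`-fold
change in expected magnitude.

## Synthetic-data generator

The generator defines the study conditions; defaults are fixed at the
regime the framework is meant to operate in: 157 species, 1–5 records per
species (~490 records), record lengths 10 + Geometric(0.18) capped at 35
years (mean ≈ 15, median ≈ 13), weather window 1979–2013, ᾱ = 0.02,
σ²_PHYLO = 0.01, σ²_SPECIES = 0.2, record-level residual sd 0.85 (so signed
effects have roughly unit variance), β_N = 0.12; for magnitude generation,
log-scale life-history slopes (−0.20, +0.16, −0.02) for longevity, litter
size and body mass, a record-length slope −0.30 and Gamma shape 1.5.

Components: a pure-birth (Yule) ultrametric phylogeny with depth normalized
to 1; log-normal life-history traits with log-scale correlations
corr(lnL, lnM) = +0.7, corr(lnL, lnS) = −0.5, corr(lnM, lnS) = −0.4 (the
fast–slow pattern; configurable, litter size floored at 1); monthly weather
as mean + seasonal sine + slow linear trend + iid anomalies, with the
injected per-year anomaly means stored as ground truth; record effects drawn
from the exact hierarchical structure of the meta-regressions (per-species
intercepts and phylogenetic deviations, *not* per-record species noise, so
the fitted variance components are recoverable); and log-abundance dynamics
`x_{t+1} = x_t − dd·(x_t − x̄) + ω·W_t + N(0, σ²_process)` with optional
log-normal observation noise and rounding (zeros possible, so the zero
filter is exercised).  Abundance is forced by the record's *standardized*
true annual anomaly, putting the generative ω on the same per-standardized-
anomaly scale as the estimate.  Fixing the seed reproduces every dataset
bit-for-bit.

What the generator does **not** emulate: heterogeneous sampling methods
(counts vs densities vs indices) beyond an overall scale, spatially
correlated weather between nearby records, missing years inside records,
lagged or nonlinear weather responses, and trait measurement error.  Passing
recovery tests therefore demonstrates the statistical machinery is correct
and calibrated under the stated generative regime — not that real data meet
those assumptions.

## Numerical choices and degenerate inputs

- Constant series (weather, drivers, effects) raise degenerate-input errors
  rather than returning NaNs; all-zero anomalies for a record are logged and
  skipped in batch runs.
- STL additivity is exact to machine precision; annualization requires
  complete years.
- The REML criterion guards singular penalized designs; non-finite
  log-densities during HMC reject the proposal.
- V is validated PSD (eigenvalue ≥ −1e-8) before sampling; non-ultrametric
  trees are normalized by maximum root-to-tip depth with a warning.
- LOO requires all fits to share the response vector; self-comparison yields
  Δelpd = 0 exactly and results are invariant to model-list order.

## Problem sizes

Test-suite and acceptance-script studies use: 500 replicates for stage-1
calibration (T = 30), 300 replicates per density-dependence level, a
100-record batch for estimator cross-validation, 20 replicates at the
full study scale (≈ 490 records / 157 species) for each meta-regression
recovery study, and 10 replicates for the null model-selection calibration;
meta-regression fits in these studies run 3 × 800 HMC iterations.  These
sizes keep Monte-Carlo error comfortably below the tolerances being checked.

## Known limitations

- Stage-2 ignores stage-1 uncertainty in ω (no measurement-error model).
- The AR(1)-whitened estimator is positively biased under strong density
  dependence (see above); results at dd ≥ 0.5 should be read accordingly.
- PSIS-LOO on conditional (record-level) likelihoods can show high Pareto k
  for species with few records; model rankings in the tests are robust to
  this, but refitting problematic observations is not implemented.
- The phylogeny module implements Brownian correlation only — no Pagel's λ
  or Ornstein–Uhlenbeck transformations.
- The pipeline is tabular-output only; no figure generation.
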