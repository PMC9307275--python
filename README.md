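# climpop

**Do annual weather anomalies move terrestrial-mammal populations, and does
life history decide how hard?**

`climpop` implements a two-step Bayesian meta-regression framework for
linking annual weather anomalies to population growth rates across many
long-term abundance records, and for testing whether species-level life
history (maximum longevity, litter size, adult body mass) predicts the
*absolute magnitude* of those responses.  It is aimed at population
ecologists and macroecologists working with compilations of abundance time
series (Living-Planet-style data) paired with gridded monthly weather.

Because the real inputs are large external downloads, the package ships a
first-class synthetic-data generator that emulates them with known
parameters, so every stage — filtering, anomaly extraction, record-level
estimation, and the phylogenetic meta-regressions — is verifiable by
parameter recovery.

## The model

**Stage 0 — anomalies.** Each record's monthly weather series (1979–2013) is
z-scored and decomposed with STL (seasonal window 7, trend window 1001) into
seasonal + trend + remainder.  The remainder is the *weather anomaly*; its
per-year mean `W_t` (and, as an alternative driver, the within-year variance
of the raw monthly values) enters stage 1.

**Stage 1 — record-level weather effects.** For each abundance record, with
growth rates `r_t = ln((X_{t+1}+1)/(X_t+1))`,

    r_t = β₀ + ω·W_t + f(year_t) + ε_t,    ε_t ~ AR(1)

where `f` is a low-rank penalized thin-plate-type spline (basis dimension 5)
absorbing the long-term abundance trend.  The smoothing parameter and the
AR(1) coefficient ρ are chosen by REML (grid + golden-section profiling).
Alternative estimators (linear year effect; a Kalman-marginalized state-space
model with process and observation error sampled by an ensemble MCMC)
cross-validate ω.

**Stage 2 — meta-regressions across records.**  With z-scored effects ω as
the response, the *directional* model is Gaussian,

    ω_i ~ Normal(μ_i, σ_resid),
    μ_i = ᾱ + a_SPECIES[j] + g_PHYLO[j] + β_BIOME[b(i)] + β_N·N_i,
    g_PHYLO ~ MVNormal(0, σ²_PHYLO·V),  a_SPECIES ~ Normal(0, σ²_SPECIES),

with `V` the Brownian phylogenetic correlation matrix from a dated tree, and
the *magnitude* model is Gamma with a log link on |ω| with linear z-scored-log
life-history terms selected among 10 candidate models by PSIS-LOO
(Δelpd vs the base model).  Both posteriors are sampled by Hamiltonian Monte
Carlo with analytic gradients and non-centered random effects; convergence is
checked with split-R-hat (< 1.05) and ESS, priors with prior predictive
simulation, and residual spatial structure with a permutation Moran's I test.

## Worked example

Run the full pipeline on a synthetic world whose effect magnitudes are driven
by life history (longevity slope −0.20, litter slope +0.16, body-mass slope
−0.02 on the log mean of |ω|):

```sh
cat > demo.yaml <<'EOF'
mode: synthetic
outdir: demo_run
seed: 21
effect_model: gamma     # magnitudes driven by life history
models: [base, longevity, litter, additive]
variables: [temp]
EOF
climpop run-all --config demo.yaml
```

which prints (about 40 s):

```
   variable                     quantity     value    ci_low   ci_high    note
temperature         alpha_bar (Gaussian) -0.012420 -0.208842  0.181777     NaN
temperature               sigma2_species  0.032421  0.001008  0.101560     NaN
temperature                 sigma2_phylo  0.025917  0.000851  0.093231     NaN
temperature            beta_N (Gaussian)  0.016038 -0.078247  0.108604     NaN
temperature                     rhat_max  1.005083       NaN       NaN    pass
temperature beta_z_longevity (longevity) -0.273811 -0.356217 -0.186533     NaN
temperature       beta_z_litter (litter)  0.248800  0.157317  0.336628     NaN
temperature  beta_z_longevity (additive) -0.178770 -0.299654 -0.060998     NaN
temperature     beta_z_litter (additive)  0.164940  0.068059  0.257998     NaN
temperature  beta_z_body_mass (additive) -0.056824 -0.160444  0.057090     NaN
temperature        delta_elpd (additive) 18.734639       NaN       NaN     NaN
temperature       delta_elpd (longevity) 14.385941       NaN       NaN     NaN
temperature          delta_elpd (litter)  10.957646      NaN       NaN     NaN
temperature            delta_elpd (base)  0.000000       NaN       NaN     NaN
temperature                     morans_I  0.006774       NaN       NaN p=0.049
```

Reading it: the Gaussian model finds no *directional* weather effect (the
global intercept ᾱ straddles 0), while LOO strongly prefers every
life-history model over the base model and recovers a negative longevity
slope and positive litter-size slope on the magnitude of responses —
longer-lived, smaller-litter species respond less to weather anomalies, in
both cases on the scale of z-scored stage-1 coefficients.  A slope β across
Δz standardized trait units implies an `exp(β·Δz)`-fold change in expected
|ω| (`climpop.fold_change`).

The same stages are available as a library — `simulate_world`,
`prepare_records`/`growth_rates`, `process_monthly`, `WeatherGAMM`,
`GaussianMetaRegression`/`GammaMetaRegression`, `loo_compare`,
`morans_i`, `marginal_predictions` — with sklearn-style estimator objects
for everything fit-shaped.

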