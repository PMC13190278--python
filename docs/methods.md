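# Methods

## The model

`behavar` fits a bivariate double-hierarchical generalized linear model
(DHGLM) to repeated behavioral assays of individuals reared under two
developmental predator regimes ("naive" vs "exposed").  Two traits are
analyzed jointly: distance moved in a novel environment (pixels, strictly
positive) and time to emerge from a shelter (seconds, capped at 600 s).
Each observation of trait *k* for individual *i* (pool *p*, trial *t*,
group *g*) is modeled on a standardized scale as

    y ~ censored-Normal(mu, sigma^2; [L_k, U_k])
    mu        = beta0_k + betaPred_k g + betaTrial_k t + betaInt_k g t
                + betaSize_k x_size + batch offsets + betaDens_k x_dens
                + a_ik + b_ik t + m_pk
    log sigma = delta0_k + deltaPred_k g + w_ik + d_pk

The six individual-level effects u_i = (a_DM, b_DM, w_DM, a_TE, b_TE, w_TE)
— intercept ("initial behavior" / personality), trial slope (plasticity to
repeated testing) and log-residual-SD deviation (predictability) per trait —
follow a zero-mean multivariate Gaussian whose 6x6 covariance is estimated
separately per group, so predator exposure can reshape both variances and the
correlation structure (behavioral, plasticity and predictability syndromes
and the within-trait personality/plasticity/predictability correlations).
The four pool-level effects q_p = (m_DM, m_TE, d_DM, d_TE) share one 4x4
covariance across groups, since pools are nested within regimes.  There is no
residual cross-trait correlation at the observation level: the two assays are
separated in time, and cross-trait dependence enters only through u and q.

Emergence times at the 600 s cap contribute the Gaussian upper-tail
probability instead of a density (right censoring); the 0 s floor is handled
symmetrically as left censoring.  All tail terms are evaluated through the
log-CDF so the likelihood is stable arbitrarily far into the tails.

Priors are weakly informative: N(0, 1) on every fixed effect,
half-Student-t(3, 0, 2.8) on every random-effect SD, and LKJ(2) on the
correlation matrices.

### Derived quantities

All derived quantities are computed per posterior draw and only then
summarized (posterior mean and 95% highest-posterior-density interval);
ratios and exponentials do not commute with expectations, so plugging
posterior means into the formulas gives slightly different values than the
draw-wise path reported here.

* Within-individual (residual) variance per group and trait:
  `V_res = (exp(m + v/2))^2 = exp(2m + v)`, where m is the dispersion fixed
  part (including the predator term for the exposed group) and v the
  among-individual variance of log residual SD.  This is (E[sigma])^2, the
  square of the expected residual SD, not E[sigma^2].  Pool-level dispersion
  variance is excluded (and the exclusion is recorded in the output
  metadata): the quantity characterizes a typical individual in a typical
  pool.
* Adjusted repeatability `R = V_among / (V_among + V_res)` per group/trait.
* Group contrasts ("Delta Exposure") are exposed-minus-naive draw-wise; for
  population-level rows the contrast is the predator coefficient itself.
* Significance conventions: a signed quantity is flagged when its 95% HPDI
  excludes 0; a variance is flagged when the lower HPDI bound exceeds 0.01.
* HPDIs are the shortest contiguous window containing ceil(0.95 n) sorted
  draws.  BLUP tables report each individual's posterior mean and posterior
  mode (Gaussian KDE with Silverman's bandwidth, overridable) of the six
  random-effect components.

## Preprocessing

Distance moved is log-transformed (strictly positive, multiplicative error)
then z-scored; emergence time is z-scored untransformed.  The z-scoring
statistics are computed over observation rows with censored values included
at their bound — this mirrors what a formula-based fitting interface sees in
the response column — and the censoring bounds are pushed through the same
affine maps, so U_TE = (600 − mean_TE)/SD_TE.  Size and conspecific density
are individual-level covariates and are centered/scaled over individuals'
unique values (switchable to observation-level scaling).  Nonpositive
distances abort with an error naming the offending rows; a documented
`log_offset` flag exists but is off by default because distance is a strictly
positive measurement.  Batch is a 5-level categorical with batch 1 as the
reference.  All scaling metadata is retained, making every transform exactly
invertible; `true_params_on_prepared_scale` maps generator-scale parameters
onto the fitted scale through these affine maps, which is what makes exact
parameter-recovery checks possible.

## Synthetic data

The generator reads the model forward at the study design: 169 naive
individuals in 4 pools and 48 exposed individuals in 8 pools, 5 experimental
batches, 4 trials of both assays, ~9% of individuals dropping out after a
uniformly drawn trial (missing completely at random, emulating
metamorphosis/mortality losses).  The `paper_like` preset sets every fixed
effect, variance component and correlation to the field posterior means; the
two printed correlation matrices are positive definite as printed (smallest
eigenvalues 0.045 and 0.127) and are used verbatim.  A slope variance printed
as 0.00 is taken as 0.004 — a small nonzero value at the boundary of printing
precision — so that interval-coverage checks remain well-defined.  The `null`
preset removes every predator effect and equalizes the group covariances;
`high_signal` doubles the mean contrasts.

Back-transforms: distance raw = exp(z·1.0 + 6.0) pixels; emergence raw =
z·130 + 420 seconds, censored at [0, 600].  The anchors are chosen so that a
typical naive individual emerges around 400 s with a realistic censored
fraction (~6% of emergence rows).  Values reaching the cap are recorded at
600 s and flagged right-censored.  Values reaching the floor are flagged
left-censored by default, which matches the observation model's bounds; with
`left_censor=False` the generator instead draws truncated noise that never
crosses the floor — that variant is *not* the model the sampler assumes, and
measurably biases dispersion-SD recovery, so it is off the default path.
The density covariate is the pool census drawn per regime and rescaled so
each regime's pools reproduce the field sample moments exactly (54.25 ±
30.84 naive, 6.50 ± 9.38 exposed; clipped at 1): the reported figures are
realized pool statistics, and reproducing that spread is what keeps density
identifiable next to the predator indicator, as it was in the field design.

What the generator does not emulate: video-tracking measurement error,
observer scoring error, non-Gaussian residuals, within-day carry-over between
the two assays, and any selective (non-random) dropout.  Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to real-data violations of them.

## Posterior computation

The sampler is a blocked MCMC kernel written for this model's structure
(any kernel meeting the convergence thresholds is conformant; a
gradient-free kernel was chosen so the whole pipeline runs on plain
numpy/scipy):

1. **Censored-data augmentation.**  Censored responses are imputed from
   one-sided truncated normals via the inverse log-CDF, after which the
   observation model is linear-Gaussian in the latent responses.
2. **Conjugate Gibbs blocks.**  Mean fixed effects (per trait) and the mean
   components of every individual and pool effect vector have exact Gaussian
   full conditionals; per-individual 4x4 blocks are conditionally
   independent and updated in one vectorized batched solve.
3. **Adaptive Metropolis blocks.**  Dispersion fixed effects (2-dim blocks
   with Haario empirical-covariance proposals), individual/pool log-SD
   components (vectorized per-unit proposals with Robbins-Monro scale
   tuning), and the variance components: a 6-dim log-SD block plus scalar
   scans over the 15 unconstrained correlation parameters per group
   (canonical-partial-correlation parameterization with exact Jacobians).
   The group-covariance conditional depends on the random effects only
   through their 6x6 scatter matrix, so these scans cost O(1) in the data.
4. **Recentering moves.**  Each fixed effect is translated jointly with the
   random effects it is confounded with (intercepts with a and m, trial
   slopes with b, dispersion intercepts with w and d; predator terms with
   the exposed subset).  The likelihood is invariant along these directions
   and the shift has an exact Gaussian conditional under the priors — this
   removes the classic random-walk behavior of hierarchical intercepts.
5. **Interweaving (ASIS).**  Holding the standardized effects fixed, the
   SDs are re-updated non-centered: jointly (adaptive 6-dim block) and, per
   component, by univariate slice sampling — scaling u[:, c] and s_c
   together leaves the standardized effects invariant, so the slice target
   is the observation likelihood plus the half-t prior alone.  The slice
   moves traverse the full conditional without tuning and are what defeats
   the funnel between variance components and effects.  The correlation
   parameters get the analogous non-centered scalar scan on alternate
   sweeps.

Adaptation (proposal covariances and scales) runs during burn-in and is
frozen afterwards, so retained draws come from a fixed Markov kernel.  One
master seed drives everything; per-chain seeds are spawned deterministically,
and identical seed + configuration reproduce byte-identical draws and report
files.  Chains are initialized from trait-wise least squares with
overdispersed jitter.

The full configuration is 4 chains x 8,000 iterations with 3,000 burn-in and
thinning 10 (2,000 retained draws).  Convergence is assessed post-thinning
with arviz's rank-normalized split R-hat (< 1.1), effective sample size, and
lag-1 autocorrelation (< 0.1); degenerate (constant) parameters are reported
as undefined and flagged.  Diagnostics cover every stored scalar, including
individual effects.

### Reduced configurations

Two documented reduced configurations exist for fast runs: the *test-scale*
config (4 chains x 1,500, burn-in 500, thin 2) used by the acceptance script
and single-fit checks, and the *replicate* config (2 chains x 900, burn-in
300, thin 3) used by the repeated-simulation studies in the test suite
(20-replicate parameter-recovery and type-I checks at the full 217-individual
design).  These sizes keep the complete validation suite within a desktop
time budget; at the replicate scale the slowest-mixing correlation
parameters retain effective sample sizes of only a few dozen, which is
adequate for interval-coverage checks pooled over parameters and replicates
but not for publication-grade estimates — use the full configuration for
real analyses.

## Numerical notes

* Correlation matrices are parameterized by their Cholesky factor through
  tanh-transformed canonical partial correlations; the LKJ density is
  evaluated on the factor with the standard change of variables, and the
  transform's log-Jacobian has a closed form.
* `log(1 - Phi(z))` is never formed directly; all tail quantities go through
  `log_ndtr`/`ndtri_exp`.
* Zero-variance components degenerate cleanly: the generator factors the
  correlation matrix and scales by the SD vector, and repeatability with
  both variances zero raises rather than returning NaN.
* Degenerate draw vectors (all equal) yield a zero-width HPDI at that value
  and mode = mean.

## Known limitations

* The supplementary decomposition of predictability variance attributable to
  mean-level variation is out of scope (its method is not described in the
  material this package implements).
* The dispersion submodel carries no trial slope at any level, and response
  families other than the (censored) Gaussian are not supported.
* Pool-level dispersion variance is excluded from the within-individual
  variance by construction (see above); including it would raise V_res
  slightly for pool-variable datasets.
* Published field estimates for this design carry wide intervals for the
  exposed group (n = 48); single synthetic replicates at that size recover
  those components with correspondingly wide posteriors.
* Because every summary is computed draw-wise, small discrepancies from
  plug-in arithmetic on rounded posterior means are expected; the same
  draw-wise repeatability can legitimately round to 0.23 or 0.24 depending
  on where in the workflow it is rounded.  This package always reports the
  draw-wise value.
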