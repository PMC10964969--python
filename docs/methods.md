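# Methods

## Model

The package fits a Bayesian logistic regression whose mixture effects are
spatially varying coefficients. For subject *i* at location *s_i*:

    Y_i ~ Bernoulli(p_i)
    logit(p_i) = β_i0 + Σ_j β_ij Σ_k ω_jk q_ijk + Σ_b θ_b x_ib

Each mixture *j* contributes through a *group index*, the ω-weighted sum
of its quantile-scored components. Weights are positive and sum to one, so
the index lives on the same 0..Q−1 scale as a single scored component and
β_ij is interpretable as the log-odds change per quantile increase of the
whole mixture at location *s_i*.

Priors:

* spatial fields (intercept and one per mixture): mean-zero multivariate
  normal with covariance (1/τ)·Ω(ρ), where Ω is the Matérn-3/2 correlation
  matrix, entries (1 + d/ρ)exp(−d/ρ) in Euclidean distance d. The model is
  deliberately parameterised with covariance *proportional to the
  correlation matrix* (precision τ·Ω⁻¹): a covariance proportional to Ω⁻¹
  would invert the meaning of the correlation decay.
* one shared range ρ across all fields, uniform over the observed
  inter-point distance range [d_min, d_max] (degenerate geometry — all
  points coincident — is rejected).
* weights ω_j ~ Dirichlet(α), α = 1 by default (non-informative).
* covariate effects θ_b ~ N(0, σ_b²), σ_b ~ Uniform(0, 10); field scales
  σ_β = τ^{−1/2} ~ Uniform(0, 10). Scale priors are evaluated on the σ
  scale throughout.

Only the Bernoulli/logit case is implemented; the linear predictor would
be unchanged under other outcome families (that extension is out of
scope here).

### Quantile scoring

Components are scored column-wise into Q bins (default Q = 4, quartiles)
using the Q−1 interior *in-sample* quantiles as right-closed break points;
ties share the score of their interval, and a constant column is an error
rather than an arbitrary score. Scoring by sample quantiles makes the
model invariant to strictly monotone transformations of each raw
concentration (verified by property test).

### Spatially varying intercept

The intercept β_0 is a GP field with its own precision by default, the
same prior family as the mixture fields. A constant intercept is available
(`spatial_intercept=False`); it is then treated exactly like an adjustment
covariate, with a N(0, σ²), σ ~ U(0, 10) prior.

## Posterior computation

The posterior is simulated natively (no external MCMC engine) with a
block sweep per iteration:

1. **GP fields** — elliptical slice sampling, which uses the MVN prior
   exactly, needs no step-size tuning, and always terminates (angle
   shrinkage brackets the current state).
2. **Weights ω_j** — random-walk Metropolis on the additive-log-ratio
   transform (C_j − 1 free coordinates) with the log-Jacobian Σ_k log ω_k,
   scale adapted toward 0.234 acceptance (0.44 when only one free
   coordinate).
3. **Covariate effects θ_b** — scalar adaptive random walks, target 0.44.
4. **Range ρ** — reflective random walk inside [d_min, d_max]; each
   proposal re-factorises Ω(ρ) (the Cholesky is cached otherwise). The
   Metropolis ratio uses the MVN prior density of every field.
5. **Scales** — reflective random walks on (0, 10) for each σ_β and σ_b.

Adaptation is Robbins–Monro on the log proposal scale and runs during
burn-in only, so the retained chain is a time-homogeneous Markov chain.
Chains are initialised overdispersed: fields from the prior at σ_β = 1,
ω ~ Dirichlet(α), θ ~ N(0, 1), ρ uniform on its bounds. Everything is
reproducible bit-for-bit from the configuration seed (chain seeds are
spawned from it).

Defaults are desk-scale — 2 chains × (2000 burn-in + 2000 retained),
thin 1 — and deliberately small; production analyses should scale the
iteration counts up by one to two orders of magnitude via `SamplerConfig`.
Convergence is judged by the classic two-chain Gelman–Rubin PSRF with the
< 1.1 rule; a PSRF with zero within-chain variance is reported as
undefined rather than silently passed. With the likelihood switched off
(`use_likelihood=False`) the sampler reproduces its priors — Dirichlet
moments for ω, uniform ρ — which the test suite checks; note that ρ mixes
slowly in prior-only runs with many locations because the fields strongly
inform it, so those checks use few locations and heavy thinning.

### Grid prediction (kriging)

For each retained draw, the field values, ρ and τ of that iteration define
the conditional MVN of the field at the 30×30 grid of cell centres, and
one *joint* draw is taken (not a posterior-mean plug-in), so posterior
uncertainty propagates into grid-cell exceedance probabilities. The
conditional mean map and the correlation-scale Schur-complement Cholesky
are computed once per iteration and shared across fields. A `grid_thin`
knob subsamples retained iterations for this step only (default 1 = every
draw); a few hundred pooled grid draws already give exceedance
probabilities with Monte-Carlo error well below the 0.95 decision margin.

### Numerical choices

* Diagonal jitter 1e−6 on every correlation matrix before factorisation
  (configurable); Cholesky failures escalate the jitter ×10 up to six
  times before aborting with a diagnostic.
* When the conditional covariance is numerically zero (predicting at the
  observation locations with jitter 0) the draw returns the conditional
  mean exactly — interpolation rather than a spurious factorisation error.
* Bernoulli log likelihood uses the log-sigmoid form
  y·η − log(1 + e^η) via `logaddexp`; non-finite η is an error.
* Support violations in the prior return −∞ rather than raising, so the
  samplers and `log_posterior` compose safely.
* Exceedance counts draws *strictly* above/below zero; draws exactly zero
  count toward neither direction (a measure-zero event under the
  continuous posterior).
* Chains are pooled before summarisation (post-convergence practice);
  per-chain draws remain available for diagnostics.

## Synthetic-data generator

The generator emulates a case-control study on the unit square:

* locations iid uniform on (0,1)² — placement is a package choice, as is
  the default n = 1000 per dataset (both configurable; every reported run
  states its n);
* six-component mixtures from multivariate normals with zero mean, unit
  variance and fixed correlation matrices (two mildly correlated blocks
  plus two independent components); component means are irrelevant
  because quantile scoring absorbs location shifts (tested);
* true weights ω1 = (0.30, 0.20, 0.20, 0.13, 0.10, 0.07) and, for the
  second mixture, ω2 = (0.45, 0.15, 0.15, 0.15, 0.05, 0.05);
* effect surfaces: constant (mean 0 for the null scenario, mean 1 for the
  second mixture of two-mixture scenarios); one-dimensional with means
  3 / 1.5 / 0 in the vertical thirds split at x = 1/3 and 2/3; radial with
  mean decreasing from 3 at the centre (0.5, 0.5) to 0 on the boundary.
  The radial decay is linear in distance, reaching 0 at radius 0.5 and
  clamped beyond — a package decision; it makes the nested evaluation
  strata (mean ≥ 2 / ≥ 1 / ≥ 0.25) concentric disks. Location-level
  effects add N(0, 0.1²) perturbation in every scenario;
* outcomes Y_i ~ Bernoulli(sigmoid(b0 + Σ_j effect·index)) with b0
  calibrated by bisection on [−20, 20] (tolerance 1e−8) so the expected
  case fraction is 1/2 — an approximately 1:1 case:control design;
* quartile scoring (Q = 4) is used when constructing the true linear
  predictor, matching the analysis convention;
* no adjustment covariates are generated (the study design the generator
  mirrors had none in simulation); covariates are exercised by unit tests
  instead.

Scenario labels are keyed by spatial pattern (`constant-null`, `one_dim`,
`radial`, `two_mix_one_dim`, `two_mix_radial`), never by opaque codes.
Generation is reproducible from (scenario, seed); per-dataset integer
seeds are derived from the scenario seed and recorded in the simulation
manifest.

**What the generator does not emulate:** spatially correlated component
concentrations, covariate confounding, non-uniform population density,
irregular study regions, measurement error and detection limits in real
exposure assays. Passing tests therefore demonstrate that the estimator
recovers effects under the stated generative model, not that it is robust
to those real-data features.

## Evaluation metrics

Per fitted dataset: MSE between the true mean surface at the subject
locations and the subject-level posterior-mean coefficients; MSE and
absolute error between true and estimated weights — the absolute error is
computed in both the mean and the median form and both are reported, with
the mean form used as the headline "weights MAE"; the proportion of
significant grid cells per stratum (thirds for one-dimensional surfaces,
nested mean ≥ 2 / ≥ 1 / ≥ 0.25 sets for radial ones, the whole region for
constant ones — counting cells significant in either direction for the
null surface and positively flagged cells elsewhere); and the Pearson
correlation between the two estimated coefficient fields in two-mixture
fits. Aggregation over a scenario's D datasets takes the median of
coefficient MSE and the mean of everything else.

## Problem sizes used in the shipped runs

The shipped test suite and `scripts/acceptance.py` run the study at
reduced scale, chosen once as the package's reference configuration:
n = 400 subjects per dataset, 2 chains × (1000 burn-in + 1000 retained),
30×30 grid kriged from every 10th retained draw, D = 2 datasets for the
null scenario and D = 1 for the others (the prior-recovery checks use
their own small configurations). At this scale the qualitative results
are stable — full power in the high-effect strata, low false-positive
rates under the null, weights MAE well under 0.12 — while a single
scenario completes in about a minute.

## Known limitations

* Importance weights are global; spatial variation in the weights is not
  modelled.
* There is no in-model test for the presence of spatial variation; a
  genuinely constant effect still pays the cost of a GP field.
* No spatial random effects alongside the coefficient fields
  (identifiability of multiple simultaneous spatial quantities is the
  concern).
* Dense Cholesky factorisations bound practical problem sizes to a few
  thousand subjects; no sparse or low-rank GP approximations.
* Isotropic, stationary Matérn-3/2 correlation only; coordinates are
  assumed planar (project geographic coordinates before fitting).
* Short chains under-explore ρ and the field scales (high PSRF); treat
  the defaults as a starting point, not a recommendation.
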