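# Methods

## The data and the estimation problem

The package targets trait data from selection experiments on *Drosophila
melanogaster* in which flies are assayed in vials. For time-to-event
traits (starvation survival, chill-coma recovery, egg-to-adult
developmental time) a vial containing 6–22 flies is inspected at
irregular times — typically every few hours during the day with one
longer overnight gap — and the raw observation is the count of flies
whose event happened in each inter-inspection interval, plus a count of
flies still event-free at the final inspection. Event times are
therefore *interval censored*, with right censoring at the assay end,
and vials (and the replicate selection lines they belong to) induce
grouped, hierarchical variation. Standard survival tooling handles
either the censoring pattern or crossed/nested random effects awkwardly;
the package's core model handles both at once.

## The interval-censored normal mixed model

For fly *j* in vial *v* of replicate line *l*, the latent event time is

    T_vlj = x_v' beta + u_l + u_v + eps_vlj
    u_l ~ N(0, sigma_line^2),  u_v ~ N(0, sigma_vial^2),
    eps_vlj ~ N(0, sigma_resid^2)

with `x_v` a treatment-coded design row over sex, selection regime
(R = reliable cue, U = uncorrelated cue, C = benign control), cold-shock
cue, starvation treatment, their two-way interactions, and optionally
the adult age (in hours) at assay start, centered at its sample mean so
the intercept keeps its reference-cell meaning. Effects are additive in
hours. The likelihood of a vial whose inspection boundaries are
`b_1 < ... < b_K` with death counts `d_1..d_K` and `c` censored flies is
multinomial over normal-CDF interval probabilities:

    log L_v = sum_i d_i * log[ Phi((b_i - mu_v)/sigma) - Phi((b_{i-1} - mu_v)/sigma) ]
              + c * log[ 1 - Phi((b_K - mu_v)/sigma) ]

with `mu_v = x_v' beta + u_l + u_v`. Intervals are half-open `(lo, hi]`
because an event is discovered at the inspection that ends its interval.
Latent times at or below the first boundary — including negative times,
which the normal model admits — fall in the first interval; this is a
documented limitation of the normal-scale likelihood, negligible when
the mean is several residual SDs above zero, as it is here. A log-normal
response (`ModelSpec.family = "lognormal"`) is available as a
sensitivity switch: it log-transforms the boundaries and interprets the
coefficients on the log-hours scale.

The normal-scale family is the default because the effect tables this
model reproduces are additive in hours with nearly symmetric credible
intervals, which is how such experiments conventionally report effects.

### Priors

Weakly informative and configurable per model: `beta ~ N(0, s_b)` with
`s_b` defaulting to 10x the crude response spread (the count-weighted SD
of observed interval midpoints), and half-normal(0, spread) on each of
`sigma_resid`, `sigma_line`, `sigma_vial`. At the experiment's size
(thousands of flies) these priors are dominated by the data; they exist
to regularize degenerate corners (empty cells, separation).

### Posterior computation

`fit_mcmc` runs a data-augmentation Gibbs sampler written for exactly
this likelihood:

1. each fly's latent time is drawn from its truncated-normal full
   conditional (inverse-CDF sampling, evaluated in whichever tail keeps
   `ndtri` accurate);
2. given the latent times the model is linear-Gaussian, so `beta` and
   all line effects are drawn *jointly* from their exact multivariate
   normal conditional (the cross-products of the fly-level design are
   precomputed once), and each vial effect from its scalar conditional;
3. the three SDs take random-walk steps on the log scale: the group SDs
   a centered step followed by a non-centered interweaving step (holding
   `u/sigma` fixed), and `sigma_resid` a marginal step in which the
   latent times are integrated out (the interval likelihood is used
   directly). The interweaving/marginal pair removes the slow coupling
   between scales and latent quantities that plain data augmentation
   suffers from.

Step sizes adapt during warmup only (Robbins–Monro toward 44%
acceptance), so the sampling phase is a fixed kernel. Defaults are
4 chains x 1000 warmup + 1000 kept iterations; the test-suite and
acceptance runs use 2 chains x 500 + 500–600, which at the study's
design sizes give effective sample sizes of 100–400 per reported
parameter in a few seconds. Convergence is gated at split-chain
R-hat < 1.05 and bulk ESS > 100 per reported parameter (computed via
arviz); failures are warned about and flagged on the summary, never
silently passed.

### Verification

Three independent oracles check the implementation:

* `interval_log_prob` against a 40-digit error-function oracle (mpmath)
  on randomized `(mu, sigma, lo, hi)` grids, at 1e-10 absolute; interval
  partitions of the real line must exponentiate and sum to 1 at 1e-10.
* `grid_posterior_oracle` computes posterior moments for models with at
  most two free parameters by deterministic quadrature with the same
  priors; `fit_mcmc` must agree within 3 Monte Carlo standard errors.
* Parameter-recovery: simulating at the study's published design and
  effect sizes and refitting must cover each generating coefficient's
  95% CI in >= 15/20 replicates with |bias| < 2.5 h.

## Fecundity: negative-binomial mixed regression

Per-female one-day egg counts are overdispersed; they are modeled as
NegBin(mean `exp(x'beta + u_line)`, shape `k`) in the mean–shape
parameterization (variance = mu + mu^2/k), chosen because it is the
common mixed-model convention. Early (4/7-day, pooled, with no
age-class term) and mid-life (14-day) counts are separate models, with
the benign control regime as reference. The posterior is sampled with
the package's generic blocked sampler: a Laplace-mode independence
proposal (multivariate t, df = 6) updates the log-concave
`(beta, z_line)` block jointly — accepted ~90–95% of the time, giving
near-independent draws — backed by adaptive random-walk and site-wise
updates that guarantee local moves whenever the independence proposal
misfires, and scalar log-scale steps with a centered/non-centered
interweaving pair for `sigma_line`. The dispersion prior is
half-normal(0, 1) on `1/k`, so the Poisson limit `k -> infinity` remains
reachable when the data are equi-dispersed (verified: Poisson-simulated
data drive the dispersion estimate above any moderate threshold and the
coefficients match a Poisson GLM).

## Egg-to-adult survival: binomial mixed regression

Per-vial (eclosed, eggs) counts get a logit-link binomial mixed model
with a line random intercept (a vial-level intercept is available via
`random_groups`; it is off by default because the per-vial counts are
the observation unit). The same Laplace-backed sampler is used.
Zero-trial vials are excluded with a log entry; complete separation is
handled by the normal prior and flagged in the summary notes.

## Physiology traits: Gaussian LMM

Feeding, weight and metabolite traits have exactly one value per line
per sex, so the line random intercept is identified by the covariance
between a line's two sex measurements. This classical case is fitted by
REML via statsmodels MixedLM (fixed effects regime, sex, regime x sex);
estimates are cross-checked in the tests against closed-form OLS on
balanced noise-free data and against lme4's `lmer` via Rscript.

## The synthetic-experiment generator

The generator produces data under exactly the fitted models'
assumptions, at the study's design: 3 regimes x 6 replicate lines;
for starvation survival 216 vials per sex of 18–22 flies (6 per
line x cue cell), inspection every 4 h with a 12 h overnight gap, assay
ends 96 h (females) / 72 h (males) so baseline mortality is near 50%;
fixed effects default to the published estimates (intercept 104.64 h,
SexM −25.80, SelU −3.89, SelC −17.92, CueCs −7.56, SelC:CueCs +3.58).
Developmental time uses 288 vials of 6–9 individuals (reported: 295
averaging 7.6) with the published effect set around a 235 h intercept;
fecundity uses 360 females (reported: 339/312) at log-intercepts
2.97/2.56 with line SD 0.1; egg-to-adult survival uses ~80% baseline
eclosion with a −0.5 logit regime effect at the same vial scale.

Values the source experiment does not print are fixed generator
choices, documented here and held constant: variance components
sigma_resid = 20 h, sigma_line = 3 h, sigma_vial = 5 h (10/2/3 h for
developmental time), chosen so that ~50% mortality by the assay end is
plausible and the random effects are detectable; the adult-age
covariate is uniform on 72–78 h and centered, with slope 0 unless set.
These are inputs to recovery tests, not claims about the original data.

What the generator does *not* emulate: the multigenerational selection
response itself (no allele frequencies, no reaction-norm evolution),
non-normal latent-time shapes, inspection-time recording error, or
between-vial heterogeneity in schedules beyond the sex-specific ends.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions — not robustness
to model misspecification in real data.

## Numerical choices

* `log[Phi(b) − Phi(a)]` is evaluated as a log-difference of `log_ndtr`
  values on whichever side of the origin is better conditioned
  (`Phi(b) − Phi(a) = Phi(−a) − Phi(−b)`), so deep-tail intervals stay
  accurate to ~1e-12.
* Truncated-normal draws clamp the inverse-CDF argument away from 0/1
  and clip the result into the interval, guarding the (never observed
  in practice) double-underflow corner.
* Zero-length or non-increasing intervals are rejected at validation,
  never repaired.
* Zero-count intervals are dropped from the likelihood rows (they
  contribute exactly zero).
* Ties at an inspection boundary belong to the interval that ends there
  (half-open convention).
* The recovery harness derives per-replicate seeds from one
  `SeedSequence`, so studies are reproducible end to end; all samplers
  are bit-reproducible given (data, seed, settings).

## Design choices that were genuinely open

* Whether non-significant terms were dropped from the original fits or
  merely omitted from the published tables is unknowable from the text;
  the package fits the full model and treats "significant only" as a
  reporting filter (`render_effect_table(significant_only=True)`).
* The response family (normal vs log-normal hours) is a reconstruction;
  normal is the default for the reasons above, log-normal is one switch
  away.
* The age covariate enters linearly and only where a trait's
  `ModelSpec` includes it (starvation survival by default).
* The exact column layout of externally deposited tables is not fixed
  anywhere; ingestion goes through a YAML-configurable column/level
  mapping (`ColumnMap`) rather than hard-coded names.

## Problem sizes used in the checked runs

The test suite and the acceptance script run the full published design
(432 survival vials / ~8,600 flies; 288 developmental-time vials /
~2,160 individuals; 360 females; 288 eclosion vials) with 2-chain
samplers and 6–20 replicate experiments per study, sizes at which the
whole suite completes in minutes on one CPU while leaving Monte Carlo
error well inside every stated tolerance.

## Known limitations

* The normal latent-time model puts (tiny) mass on negative times.
* Single-chain runs cannot produce R-hat/ESS; diagnostics are marked
  unavailable rather than fabricated.
* The Gaussian LMM's CIs are Wald-type (REML), not posterior quantiles.
* `grid_posterior_oracle` supports at most two free parameters — it is
  a verification instrument, not an estimator.
* With 6 lines per regime, regime-level contrasts have few effective
  degrees of freedom; their CIs are honest but wide, matching the
  design's real limitation.
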