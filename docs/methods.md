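# Methods

## Model and estimation

The core model is a linear latent growth curve over four measurement waves.
Each participant carries a latent intercept and slope; both regress on an
experimental-arm indicator and a gender indicator, with bivariate-normal
deviations `(u0, u1) ~ N(0, Ψ)` and iid residuals `N(0, σ²_e)` per wave.  The
slope multiplies the transformed time `F_t = log2(months_t + 1)`, which maps
the wave times 0/1/2/3 months onto loadings 0.000/1.000/1.585/2.000.  The
log basis is a substantive choice, not a convenience: symptom change is
typically rapid early and decelerating later, which a concave loading captures
while keeping the model linear in its parameters.

Stacked over waves, the implied distribution is
`Y_i ~ N(μ_i, Λ Ψ Λᵀ + σ²_e I)` with `Λ_t = (1, F_t)`.  Missing waves are
handled by full-information maximum likelihood: participant *i* contributes
the normal density of their observed sub-vector under the corresponding
sub-mean and sub-covariance.  This is consistent under data missing at random,
so incomplete cases are retained rather than listwise-deleted.

Numerical conventions in the likelihood:

* a jitter of **1e-4** is added to the diagonal of each observed sub-matrix
  immediately before inversion, keeping it positive definite;
* if the jittered matrix is still singular, a pseudo-inverse is used and the
  log-determinant is replaced by the pseudo-log-determinant (product of
  eigenvalues above 1e-12, null directions dropped), which keeps the
  likelihood finite rather than failing;
* participants with zero observed waves contribute exactly 0;
* rows are grouped by (missingness pattern × covariate combination) so the
  likelihood costs one Cholesky solve per group, not per participant.

**Maximum likelihood.**  L-BFGS-B maximises the likelihood with fixed effects
unbounded and variances bounded below at 1e-8.  Internally the
intercept–slope covariance is parameterised through the correlation
(|r| ≤ 0.999) so box bounds keep Ψ positive semidefinite.  Initial values:
intercept grand mean at the observed baseline mean, slope terms at 0, the
observed outcome variance split equally across the three variance components,
covariance 0.  A second start uses a crude moment split (baseline variance
against change-score variance) because the equal split grossly overstates the
slope variance and can strand the optimiser on a local maximum at the
`var_e1 = 0` boundary; the better optimum is kept, followed by restart polish
passes.  Standard errors come from the inverse of the negative numerical
Hessian (central differences with step `1e-4·(1+|θ|)`, variance components on
the log scale for stability; pseudo-inverse fallback with the same jitter
rule).  Wald z, two-sided p and `estimate ± 1.959964·SE` CIs are reported for
each free fixed effect.  Non-convergence is reported on the result object,
never raised.

**Bayesian route.**  The same likelihood can be explored by an adaptive
random-walk Metropolis sampler: Gaussian proposals whose global scale adapts
toward a 0.234 acceptance rate and whose shape adapts to the empirical
covariance of recent warmup draws; adaptation freezes after warmup so retained
draws form a valid Markov chain.  Default priors are weakly informative and
scale with the data: Normal(0, 10·sd(y)) on fixed effects (the grand intercept
centred at the observed mean), half-Normal(0, 5·sd(y)) on SD-scale variance
parameters, Uniform(−1, 1) on the intercept–slope correlation.  Chains are
split deterministically from one integer seed; runs are bit-reproducible.

**Diagnostics.**  Split-chain Gelman–Rubin R̂ uses the standard
between/within-variance definitions; two constant chains at different values
give +inf rather than an error.  WAIC is computed from the pointwise
log-likelihood matrix with the sample-variance (n−1) penalty — the convention
of the reference R implementation; note some libraries use the population
variance, differing by p/S.  LOO uses importance sampling with weights
truncated at `mean·S^{3/4}`; units whose largest normalised weight exceeds 0.5
are flagged unstable.  Both criteria are always reported on labelled elpd and
deviance (−2·elpd) scales, never as a bare signed number, because published
values in this literature are ambiguous about sign and scale.

## Effect sizes and descriptive statistics

The headline effect size is the standardized mean difference of change
scores: between-arm difference of mean (wave 4 − wave 1) changes divided by
the pooled n−1 SD of within-arm changes.  The denominator is the standard
pooled SD of change scores; a degenerate zero pooled SD with unequal means
yields signed infinity flagged by the caller.  Cohen's *d* for baseline
comparisons is reported unsigned by default (magnitude convention of baseline
tables) with a signed variant.  The 2×2 chi-square defaults to the uncorrected
Pearson statistic with a Yates option — published values in this setting fall
between the two conventions, so neither is asserted as ground truth — and
φ = √(χ²/N) exactly satisfies φ²·N = χ² on the uncorrected path.  Change-score
correlation matrices use pairwise-complete Pearson r with two-sided p and
significance stars at .05/.01; every statistic is complete-case for exactly
the quantities it needs.

## Questionnaire scoring

The 16-item QIDS is scored onto the 0–27 metric by the standard 9-domain rule
(max over the four sleep items, max over the four appetite/weight items, max
over the psychomotor pair, the six remaining items as-is); a plain 16-item sum
is available as a sensitivity variant.  The Brief LSAS is taken as fear +
avoidance ratings (0–3) over 14 situations, raw range 0–84, rescaled by 24/14
onto the full 24-item LSAS metric; the rescaling multiplies before dividing so
the raw score 17.5 lands exactly on the clinical cut-off of 30.  Cut-offs are
inclusive: depression at QIDS ≥ 6, social anxiety at adjusted LSAS ≥ 30.  The
subgroup rule "social anxiety" uses the *physical*-community scale: with
baseline mean ≈ 46 and SD ≈ 23 it reproduces the ~85% prevalence this
population shows, which the virtual scale (mean ≈ 28) cannot.

## Synthetic-trial generator

The generator draws complete trials with the structure the analysis assumes:
1:1 Mersenne-Twister randomization, ~75% female, age N(23.68, 10.44²) clipped
to 9–82, outcomes generated exactly from the growth model above, behaviour
counts lognormal on the log2(count+1) scale (so the analysis transform is
exactly normal) rounded to integers, with a discrete power-law (zipf)
alternative whose exponent is a free parameter.  Questionnaire dropout is
applied per wave to the whole battery, missing completely at random by
default, with a missing-at-random option in which the dropout odds increase
with the participant's current depression level.  Behaviour counts are never
missing (they emulate server logs).  Rewards follow the 500/200/200/500 JPY
wave payments plus a 500 JPY bonus per month: experimental-arm bonus months
are Binomial(3, 0.73) (the observed completion rate in this setting) and
waitlist months Binomial(3, lottery p = 0.73), giving a maximum total of
JPY 2900.

Default truth values were fixed once, before any testing, to mirror the
magnitudes of the emulated trial's published tables.  For depression the
variance components solve two published constraints simultaneously: a slope
arm effect of −0.319 *and* an implied change-score SMD of −0.12 require a
change-score SD of 2·0.319/0.12 = 5.317, i.e. `ΔF²·var_e1 + 2·var_e2 =
28.27`; with `var_e1 = 1.0` that gives `var_e2 = 12.133`, and `var_e0 = 24.6`
reproduces the baseline SD ≈ 6.06.  Social-anxiety and count-model defaults
mirror the corresponding table magnitudes.  The wave-wise dropout default
(0, 0.10, 0.15, 0.20) is a realistic web-trial profile chosen once (the
emulated study does not publish attrition).  These defaults are study
conditions for demonstrations and tests, not assertions about any real data.

An optional correlation ρ between one behaviour's log2 change and one
outcome's change is built by replacing the wave-4 behaviour shock with
`√2·ρ·z + √(1−2ρ²)·u`, where `z` is the participant's standardized latent
outcome change; the realized correlation equals ρ exactly, valid for
|ρ| ≤ 1/√2 and only under the lognormal count family.

**What the generator does not emulate.**  Outcomes are continuous Gaussian
draws, not integer-valued questionnaire totals truncated to the instrument
range — rounding/truncation would bias recovery checks and is not part of the
analysis model.  Counts have an exactly lognormal log2 margin rather than an
empirical power law with unknown exponent and cut-off.  There is no
recruitment funnel, no within-month behavioural dynamics, and no
treatment-effect heterogeneity beyond the random slopes.  Passing tests
therefore certify the *analysis chain* under its own assumptions, not the
behaviour of the method on real trial data.

## Problem sizes used by the checks

The likelihood oracles run on n ≤ 8 fixtures against an independent dense
multivariate-normal implementation (complete data, 1e-8) and numerical
marginalisation (missing data, 1e-10).  Parameter recovery uses 300 simulated
trials at n = 500/arm with complete data (mean bias of the slope arm effect
< 0.02; 95% Wald coverage in 93–97%); 300 replicates rather than the minimum
200 tighten the Monte-Carlo noise on both checks.  SMD recovery uses one trial
at n = 5000/arm under the default dropout.  Sampler diagnostics use two chains
of 6000 retained draws (4000 warmup) on an 80-participant model without
covariate effects, where split-chain R̂ ≤ 1.01 across parameters.

## Known limitations

* The residual variance is homoscedastic across waves by design; wave-specific
  residuals are a plausible extension the interface anticipates but does not
  implement.
* Wald inference relies on asymptotic normality; near variance boundaries
  (slope variance ~ 0) the multi-start guards the optimum but the usual
  boundary caveats on variance-component inference still apply.
* The Metropolis sampler is adequate for the ~10-parameter posteriors here but
  is not a substitute for gradient-based samplers on larger models.
* IS-LOO uses truncated rather than Pareto-smoothed weights; unstable units
  are flagged so users can fall back on WAIC.
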