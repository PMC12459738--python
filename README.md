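# lgcmtrial

Latent growth curve analysis of two-arm longitudinal trials, built for the
setting of an in-game behavioral-activation intervention: two randomized arms
(~550 participants each), four questionnaire waves at 0/1/2/3 months
(depression via the 16-item QIDS, social anxiety via the Brief LSAS in virtual
and physical contexts), heavy-tailed game-behaviour counts (bell rings, avatar
customizations), wave-wise dropout, and a completion-bonus / lottery reward
scheme.  It is aimed at trial statisticians and methods researchers who want
the full analysis chain — scoring, growth modelling under missing data, effect
sizes, Bayesian fit diagnostics — as tested, reusable Python, together with a
synthetic-trial generator so every stage can be exercised without access to
any real participant data.

## The model

Participant *i*'s outcome at wave *t* follows a latent growth curve with
log-transformed time:

```
Y_it  = B0_i + B1_i · F_t + e_it,           e_it  ~ N(0, σ²_e)
B0_i  = β00 + β0exp·Gexp_i + β0fem·Gfem_i + u0_i
B1_i  = β10 + β1exp·Gexp_i + β1fem·Gfem_i + u1_i,   (u0, u1) ~ N(0, Ψ)
F_t   = log2(months_t + 1)                  → (0.000, 1.000, 1.585, 2.000)
```

`Gexp` indicates the experimental arm and `Gfem` gender; `β1exp` is the
intervention effect on the symptom slope.  The concave time basis encodes the
fast-then-slow pattern typical of symptom change.  Estimation uses
full-information maximum likelihood (FIML): each participant contributes the
multivariate-normal density of their *observed* waves only, so incomplete
cases are never dropped.  Before each sub-matrix inversion 1e-4 is added to
the diagonal, with a pseudo-inverse/pseudo-determinant fallback if it is still
singular.  Point estimates come from bounded L-BFGS-B with Wald z tests and
95% CIs; the same likelihood can instead be explored by an adaptive
random-walk Metropolis sampler, yielding split-chain R̂, WAIC and LOO (always
reported on labelled elpd and deviance scales).

The trial effect size is the standardized mean difference of change scores,

```
SMD = (ΔY̅_exp − ΔY̅_wait) / s_pooled(ΔY),     ΔY = wave4 − wave1,
```

with the pooled n−1 SD of within-participant changes — Cohen's *d* applied to
changes.  Baseline comparisons use two-sample t tests with cross-sectional
Cohen's *d* and 2×2 chi-square with φ.

## Worked example

`python examples/fit_growth_model.py` simulates a default-size trial
(548/557 participants, dropout rising to 20% by wave 4) and fits the
depression outcome:

```
converged: True   log-likelihood: -11594.8
      term     beta   95% LL   95% UL    Wald       p
       b00    7.621    6.843    8.399  19.194   0.000
     b0exp   -0.061   -0.776    0.654  -0.168   0.867
  b0female    0.704   -0.113    1.521   1.690   0.091
       b10   -0.537   -0.882   -0.193  -3.056   0.002
     b1exp   -0.344   -0.660   -0.027  -2.128   0.033
  b1female    0.177   -0.186    0.540   0.957   0.339

change-score SMD (complete cases): -0.101
SMD implied by the generating truth: -0.120
```

The generating truth sets the slope arm effect to −0.319 (implying a
change-score SMD of −0.12); the fitted `b1exp` of −0.344 with CI
(−0.660, −0.027) recovers it within sampling error, and the empirical SMD of
−0.101 sits near its implied value.  Other examples cover questionnaire
scoring (`score_questionnaires.py`), the generator (`simulate_trial.py`),
posterior diagnostics (`bayesian_diagnostics.py`), baseline tables and
change-score correlation matrices (`baseline_and_correlations.py`), and the
end-to-end report pipeline (`full_pipeline.py`).

A thin CLI wraps the same functions:

```
lgcmtrial simulate --seed 1 --out trial.csv
lgcmtrial fit --data trial.csv --outcome qids --estimator ml
lgcmtrial effects --data trial.csv
lgcmtrial pipeline --seed 1 --out-dir report/
```

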