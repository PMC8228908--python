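# Methods

## Estimand and design

The package estimates marginal risks under forced exposure,
ψₐ = E_W[P(Y=1 | A=a, W)], in a source population from which a case-control
sample was drawn with known status-specific sampling fractions q₁ (cases)
and q₀ (controls). The effect measures are RD = ψ₁ − ψ₀ (reported both as a
probability and per 100,000), RR = ψ₁/ψ₀, and the population attributable
fraction PAF = P_c(RR − 1)/RR with P_c the exposure prevalence among cases.
PAF is always below P_c for finite RR, and non-positive exactly when RR ≤ 1.

Design weights are the reciprocals of the sampling fractions. When the case
registry covers only a fraction c of incident cases, the source case count
is taken as registered/c rounded to the nearest integer before forming q₁.
The weighted empirical distribution of the sample then emulates the source
cohort, and every model fit in the pipeline multiplies these weights into
its loss. Inside variance computations the weights are normalized to mean
one; point estimates are invariant to the normalization.

## The targeting step

The initial outcome regression Q̄(A,W) is updated along the one-parameter
submodel logit Q̄_ε = logit Q̄ + εH with the clever covariate
H = A/g(W) − (1−A)/(1−g(W)). ε is fit by weighted maximum likelihood: a
Newton iteration on the score Σ wᵢHᵢ(Yᵢ − expit(offsetᵢ + εHᵢ)), run to
|score| < 1e-10 (at most 100 iterations, steps clipped to ±5;
non-convergence is flagged in the diagnostics, not raised). A single ε is
shared by both arms — one fluctuation covariate, not separate ε₁/ε₀.

One wording caveat: descriptions of this algorithm sometimes attach the two
branches of H to "cases" and "controls". The branches are by *exposure*
status (A = 1 vs A = 0); that is the reading under which the fluctuation and
standardization steps cohere, and it is what is implemented.

At the solution the design-weighted mean of the RD influence curve

    Dᵢ = wᵢ[Hᵢ(Yᵢ − Q̄*(Aᵢ,Wᵢ)) + Q̄*(1,Wᵢ) − Q̄*(0,Wᵢ) − RD]

is numerically zero (the tests require |mean| < 1e-6·sd). Standard errors
are sd(D)/√n; the RR interval is the delta method applied to
log ψ₁ − log ψ₀ with arm-specific influence contributions divided by their
ψ. Estimated propensities are truncated to [0.025, 0.975] by default
(configurable; the truncation count is reported) as standard positivity
protection.

## Super learner

Both nuisances are estimated by V-fold cross-validated stacking (default
V = 10, folds stratified on the binary target to stabilize rare-outcome
splits, fixed by the seed). The loss is the weighted negative Bernoulli
log-likelihood — the natural loss for conditional distributions of binary
variables — with held-out predictions clamped to [1e-6, 1−1e-6] so
degenerate learners keep the loss finite. Meta-weights are found by SLSQP
over the probability simplex with an analytic gradient, restarted from the
uniform point and from the best single learner; since the simplex contains
every vertex, the returned combination never has higher held-out risk than
the best single learner (+1e-8 numerical slack), and ties between vertices
break toward the lower-index learner via a 1e-12·index risk perturbation.

The registry covers the families typically used for this problem:
intercept-only, main-terms logistic, forward-stepwise logistic (weighted
AIC), logistic with all pairwise interactions, elastic-net logistic
(C = 1, l1_ratio = 0.5, standardized inputs), smooth additive logistic
(cubic B-splines, 5 knots, on columns with > 10 distinct values, ridge
1e-4), a depth-5 tree (min leaf 20), and a 200-tree random forest (min leaf
10, √p features). Tree/forest seeds derive from the fit seed. These
hyperparameters are registry defaults, recorded in the run report; a learner
that raises during cross-validation or refitting is dropped with a logged
warning and zero weight. GLM-family learners use an in-package IRLS fitter
(with offsets and a 1e-8 ridge stabilizer against separation), which also
powers the fluctuation step and the fast refits below.

## Bootstrap for the PAF

The PAF interval is a percentile bootstrap (default 10,000 replicates, the
conventional count for this interval): cases and controls are resampled with
replacement separately at their observed sizes, preserving the fixed
case-control margins, and the entire weighted TMLE plus PAF is recomputed
per replicate. Refitting the full super learner thousands of times would be
disproportionate to the smoothness of the functional, so the bootstrap
default refits the nuisances with fast weighted main-terms logistic
regressions; the nuisance function is injectable for users who want the full
library inside the bootstrap. Replicates with an undefined RR are dropped
and counted; more than 10% undefined aborts the interval.

## Synthetic cohorts

The generator emulates a registry-based study of a binary reproductive-risk
factor in adult women: 5-year age bands (20–24 … 75+) with a plausibly
decreasing population distribution, an ordered education variable and a
continuous covariate whose distributions shift with age, a binary
urbanicity covariate, a logistic exposure model (prevalence ≈ 0.5,
declining with age) and a logistic rare-outcome model (cumulative risk
≈ 1.5% over the study window, rising steeply with age). The default
coefficients give a marginal RR ≈ 1.7 and PAF ≈ 23%, the regime of the
moderate associations such studies report. Age enters the linear predictors
as the standardized band midpoint (midpoint − 45)/10; open bands use their
lower bound + 2. All randomness flows from one integer seed through a named
generator.

Frequency matching draws controls stratum-by-stratum so their age-band
distribution equals the sampled cases' distribution, with target counts
allocated by largest-remainder rounding — deterministic and auditable. The
design weights remain the status-marginal reciprocals 1/q₁, 1/q₀, mirroring
how such weights are derived in practice from registry counts; matching
therefore slightly distorts the weighted control covariate distribution for
the matching variable, which is why the calibration suites sample controls
unmatched (the matched path is exercised by its own tests). True effects are
computed exactly by enumeration when all confounders are discrete and
otherwise by ≥10⁴ Monte-Carlo draws of the covariates.

What the generator does not emulate: measurement error and recall bias,
missing data, time-to-event structure, individual (1:1) matching, multi-level
exposures, or selection mechanisms beyond the status-specific sampling.
Passing tests therefore show the estimator is correct *under the assumed
sampling design and causal model*, not that any real study's estimates are
recoverable.

## Validation suites and problem sizes

The test and analysis suites use: 200 replicates of 100k-member cohorts
sampled at 787 cases / 928 controls for bias and Wald coverage (coverage
required within [92%, 98%]); 200 replicates of 20k cohorts at 200/350 for
each double-robustness arm (bias under 3 Monte-Carlo SEs); 60k single-
binary-confounder cohorts for the saturated-model equivalence (agreement to
1e-6, observed ~1e-10); and 10,000 bootstrap replicates for the PAF
interval. These sizes make the full suite run in a few minutes while keeping
Monte-Carlo error well below the tolerances tested.

## Known limitations

- The EIC variance treats the weighted sample as i.i.d.; finite-population
  corrections for sampling without replacement are ignored (conservative at
  these sampling fractions for controls; mildly so for cases).
- A single shared ε is used; arm-specific fluctuations would change
  finite-sample behaviour slightly.
- The stepwise learner searches encoded columns greedily by AIC and does not
  group the dummies of a categorical variable.
- No missing-data handling beyond complete-case input.
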