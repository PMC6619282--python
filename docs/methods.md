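# Methods

## The problem

In clustered failure-time data (patients in centers, members of families)
and recurrent-event data (repeated infections, device failures), a popular
model is the shared frailty model: conditional on an unobserved positive
random effect Z with mean 1, each member of cluster i has proportional
hazards

    lambda(t | Z_i, x) = Z_i Y(t) lambda0(t) exp(x' beta).

Integrating Z out makes the *marginal* covariate effect time-dependent for
any finite-variance frailty law: survivors are increasingly selected for low
Z, so a conditional hazard ratio exp(beta) attenuates over time.  The same
marginal attenuation can equally be produced by a genuinely time-dependent
covariate effect with no frailty at all.  This package provides the pieces
needed to study that confounding quantitatively: a frailty calculus, a
scenario simulator, a semiparametric frailty estimator, and the diagnostic
tests practitioners would actually run.

## Frailty calculus (`families`)

Everything is driven by the Laplace transform `L(c) = E exp(-cZ)` and its
derivatives.  The posterior mean of Z given an observed history with N
events and accumulated conditional cumulative hazard `Lambda` is
`-L^(N+1)(Lambda) / L^(N)(Lambda)`; the marginal hazard ratio between
covariate groups of survivors and the median concordance
`kappa = 4 L(2 L^{-1}(1/2)) - 1` (clusters of size 2) follow from the same
object.

Parametrizations (theta > 0 the association parameter):

| family            | L(c)                                   | mean / variance    |
|-------------------|----------------------------------------|--------------------|
| gamma             | (1 + c/theta)^(-theta)                 | 1, 1/theta         |
| inverse Gaussian  | exp(theta (1 - sqrt(1 + 2c/theta)))    | 1, 1/theta         |
| positive stable   | exp(-c^b), b = 1/(1+theta), theta >= 0 | infinite variance  |
| lognormal         | quadrature (no closed form)            | 1, 1/theta         |

The positive stable scale convention is chosen so that theta = 0 is the
degenerate no-frailty boundary; a different convention is a one-line change
of `b`.  The positive stable family is the only one whose marginal hazards
remain proportional (ratio `exp(b beta)`), which is why it serves as the
"robust to nonproportionality" comparator.

Derivatives are exact recursions, not numerical differentiation: for the
inverse Gaussian, `(-1)^k L^(k)(c) = L(c) R_k(1/s)` with `s = sqrt(1+2c/theta)`
and a positive-coefficient polynomial recursion for `R_k`; for the positive
stable, `(-1)^k L^(k)(c) = L(c) Q_k(c)` with `Q_k` a finite power sum in
`c^b`.  Posterior means are evaluated as polynomial ratios in linear scale
with an automatic log-scale (logsumexp) fallback on overflow; positive
stable derivative order is capped at 30 (an explicit error beyond), which
covers every simulated design (at most 10 events per cluster).  The
lognormal family is used for data generation and marginal-hazard-ratio
curves only; its transform is computed by adaptive quadrature of the mean-1
lognormal density and is never used for fitting.

## Scenario simulator (`simulate`)

The study conditions are fixed by the generator defaults:

* binary covariate `x ~ Bernoulli(0.5)`, drawn per subject (`clustered`),
  per cluster (`clustered_common`) or per subject (`recurrent`);
* Weibull conditional intensity with shape `alpha in {0.8, 1, 2}` and
  a log-time covariate effect `beta(t) = beta0 + beta1 log t`,
  `beta0 = log 5`; the resulting conditional law is again Weibull with shape
  `alpha + beta1 x`, so event times are drawn by exact inversion;
* `beta1` levels: 0 (proportional hazards), `-beta0/(2 log 50)` ~ -0.21
  (moderate), `-beta0/log 50` ~ -0.41 (effect crossing zero at the horizon
  t = 50);
* scale fixed by `Lambda0(50) = 0.8` (clustered) or `0.8 j` (recurrent with
  j events per subject), so cells are comparable across structures;
* shared frailty: lognormal with mean 1 and variance `sigma2 in {0, 0.25}`
  (a gamma option exists for parameter-recovery checks);
* total sizes 300 / 900 / 1500 observations, cluster sizes {1, 2, 3, 5, 10}.

Recurrent processes are simulated in calendar time by inverting the
conditional cumulative intensity at unit-exponential increments.  Exactly
j event times are generated per subject and follow-up ends at the j-th
event; this informative end of observation is an essential feature of the
design — with a common administrative censoring time and no such exit, risk
sets are identical for all subjects and the frailty likelihood has
essentially no spurious-rejection behavior in these cells.

Administrative censoring is calibrated per cell: one large sample (default
1e5 subjects, its own seed stream) is generated uncensored, and the 0.7
quantile of the event times (for recurrent cells, of the pooled j per
subject) becomes the fixed censoring time of every replicate, yielding a
30% censoring rate — of subjects in the clustered designs, of generated
events in the recurrent design (where one censored row can replace several
unobserved events).

Randomness: each replicate derives a `SeedSequence` from (master seed,
cell hash, replicate index), split into frailty / covariate / event-time
substreams.  Cells are therefore order-invariant and half-grids merge
exactly into full grids.

## Cox/Breslow core (`cox`)

Newton maximization of the Breslow partial likelihood on counting-process
rows `(start, stop]`, with offsets entering the linear predictor at fixed
coefficient 1 (the EM M-step requirement).  Covariates are centered
internally; overshoot is handled by step-halving; monotone likelihood is
flagged (`separation`) rather than raised, using |beta| > 15 on the centered
scale as the criterion since the likelihood plateaus there.  Risk-set sums
for right-censored data (all `start = 0`) use O(n) suffix cumsums over rows
sorted by stop; genuine start-stop data use a dense at-risk matrix, built
once per dataset and shared across all refits (the EM performs hundreds).
Ties are Breslow throughout: simulated times are continuous, and tied times
in external data simply share risk sets.  Convergence: relative
log-likelihood change < 1e-9 or 50 steps.

## Shared-frailty estimation (`em`)

For fixed theta the EM iterates the posterior-mean E-step
`z_i = -L^(N_i+1)(Lambda_i)/L^(N_i)(Lambda_i)` with
`Lambda_i = sum_j int Y_ij exp(x_ij' beta) dLambda0`, and a Cox M-step with
offsets `log z_i` (inner tolerance: max |z change| < 1e-6, at most 200
iterations).  The profile marginal log-likelihood

    sum_i log[(-1)^{N_i} L^(N_i)(Lambda_i)]
    + sum_events [x'beta + log dLambda0]

is maximized over `log theta` on [log 1e-4, log 1e8] by bounded Brent search
(xatol 0.01), warm-starting (z, beta) between evaluations.  The search is
exact against direct joint maximization over (beta, baseline jumps) to
~1e-13 on small data (tested).

The no-frailty null lies on the boundary (theta -> infinity for gamma and
inverse Gaussian, variance 0; theta -> 0 for positive stable), so the LRT
statistic `2 [l(theta_hat) - l_null]` is referred to the mixture
`(chi2_0 + chi2_1)/2`: p = P(chi2_1 >= T)/2, rejection at 5% iff T > 2.7055.
The profile interval for the frailty variance uses the same 2.7055
threshold, which makes "lower bound exactly 0" equivalent to LRT
non-rejection by construction; a 3.84 threshold would break that
equivalence, so it is not offered.  For the positive stable family the
interval is reported on theta (no variance exists).

## Diagnostics (`diagnostics`)

*Heterogeneity (Commenges-Andersen style).*  The score statistic is
`T = sum_g (sum_{j in g} Mhat_gj)^2 - N`, squared within-cluster sums of
martingale residuals minus their estimated null expectation (equal to the
event count by the Breslow property).  Standardization differs by design:

* clustered data: moments of T under random reassignment of subjects to
  clusters — an exact conditional null, since subjects are independent under
  no frailty — estimated from 2000 vectorized shuffles; the right tail is
  evaluated with a three-moment (shifted gamma) approximation, which tracks
  an explicit permutation tail within 0.05 even at 10 small clusters and
  reduces to the normal as skewness vanishes.
* recurrent data: cluster = subject, so there is nothing to permute, and
  the exit at the j-th event makes iid-based variance formulas
  substantially wrong (the plug-in baseline also shifts the null mean of T).
  The test is instead calibrated by parametric bootstrap from the fitted
  null model: subject processes are regenerated from the estimated baseline
  and covariate effect, stopped at the j-th event or the censoring time, and
  the statistic — including the Cox refit — is recomputed (199 draws by
  default; Monte-Carlo p-value).

*Proportional hazards (ZPH).*  The standard global scaled-Schoenfeld score
test: with `g(t)` the left-continuous Kaplan-Meier transform `1 - KM(t-)`
(the historical default of the reference implementation; identity, log and
rank transforms are available), the statistic is
`u' (d V_beta) u / sum (g - gbar)^2`, `u = sum_k (g_k - gbar) s_k`, referred
to chi-square with one df per covariate.  Verified against an independent
implementation (lifelines) to ~1%.

## Pipeline (`pipeline`) and problem sizes

`run_scenario` evaluates one cell: per replicate it fits the null Cox model,
runs CA and ZPH, fits the requested frailty families, applies the mixture
LRT at 5%, and records the gamma variance estimate, whether its profile
interval covers zero (free, via the LRT equivalence), and each family's
implied median concordance at theta-hat.  Replicate failures are counted and
excluded per statistic, never propagated.  Default 500 replicates per cell;
rejection-fraction checks use 3 binomial standard errors at that count.
The package's own verification runs the four headline cells (total size
300, shape 1) at 500 replicates and the directional trend checks at
80-200 replicates with cluster sizes {2, 10} — chosen as the smallest sizes
at which the binomial bands are meaningfully narrow.

`kidney_analysis` reproduces the catheter-infection analysis sequence
(gamma frailty with no covariates / age / age+sex, the marginal Cox model,
a sex-by-time interaction model via episode splitting, the positive stable
fit, CA/LRT/ZPH p-values, and scaled Schoenfeld residuals with and without
log posterior frailty means as offsets).  The 38-patient dataset itself is
external (it ships with the R `survival` package); the loader raises an
instructive error describing the expected schema when it is absent.  The
test suite regenerates the dataset at run time through `Rscript` and checks
the fitted frailty variances, covariate effects, p-values and profile
intervals against their published values; the Cox and sex-by-time
interaction fits agree with R's `coxph` (Breslow ties) to four decimals.

## What the generator does and does not emulate

The simulator reproduces the study conditions exactly as stated above:
Weibull baselines, a single binary covariate with a log-time effect,
lognormal cluster-level frailty, administrative censoring calibrated to
30%.  It does not emulate covariate-dependent or random censoring,
continuous or multiple covariates, Gompertz baselines, gap-time recurrence
(structurally identical to the clustered design), or frailty laws beyond
lognormal/gamma.  Passing tests therefore demonstrate correct behavior of
the estimators and tests under these controlled mechanisms, not robustness
to the messier features of real data.

## Numerical choices and limitations

* Inner EM tolerance 1e-6 on posterior means balances the LRT's need for
  stable log-likelihood differences (threshold 2.7055) against hundreds of
  EM runs per fit; the outer xatol of 0.01 on log theta changes
  log-likelihoods at the 1e-5 level, well below that threshold.
* theta-hat within 5 xatol of a search boundary is flagged; a maximum not
  exceeding the null log-likelihood is reported as the boundary (variance 0,
  LRT 0).
* Lognormal quadrature nodes span +/- 12 standard deviations of log Z;
  median-concordance root searches use the bracket [1e-12, 1e6] with
  absolute tolerance 1e-10.
* The CA permutation moments are Monte-Carlo estimates (2000 shuffles), so
  p-values near the rejection boundary carry ~1e-2 Monte-Carlo noise; the
  seed is fixed by argument for reproducibility.
* Degenerate inputs: datasets without events are rejected; constant
  covariates yield beta = 0 with a singular-information flag; clusters
  without events contribute log-survivor-probability terms only.
* The likelihood-ratio rejection rate in the smallest-cluster frailty cells
  (size-2 clusters, frailty variance 0.25) is noticeably sensitive to the
  lognormal parametrization: specifying the 0.25 on the log scale instead of
  the natural scale changes the relative frailty variance from 0.25 to
  e^0.25 - 1 ~ 0.28 and shifts that cell's power by several points.  The
  generator uses the natural-scale convention (E Z = 1, Var Z = sigma2)
  throughout; anyone comparing against software that parametrizes lognormal
  random effects by the log-scale variance should account for this.
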