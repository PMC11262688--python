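# Methods

## The biological setting and the model

Ibrutinib blocks B-cell-receptor signalling in chronic lymphocytic leukemia
(CLL). One of its signature effects is *redistribution lymphocytosis*:
leukemic B cells stop homing to lymphoid tissue, exit the lymph nodes and
accumulate transiently in blood. Clinically, patients split into a
transient-hyperlymphocytosis group (tHL, absolute lymphocyte count at month 3
below its pre-treatment value) and a prolonged group (pHL, ALC at month 3
above baseline).

`cllkin` models this with six compartments, all expressed as fold-changes of
their pre-treatment value (so every trajectory starts at 1):

    dB_LN/dt = f_in - F_out * B_LN                    (leukemic B, lymph node)
    dB_bl/dt = kappa * F_out * B_LN - mu_B * B_bl     (leukemic B, blood)
    dT_i/dt  = lam_i + sig_i * F_out * B_LN - mu_i * T_i,   i in {CD4, CD8, NK, Treg}

* `F_out` (1/d) — lymph-node exit rate of leukemic B cells under treatment.
* `f_in` (1/d) — lymph-node production rate, normalised by the initial
  lymph-node burden. The absolute production rate in cells/day is
  `f_in * B_LN0`.
* `mu_B` (1/d) — death/clearance of leukemic B cells in blood.
* `kappa` (dimensionless) — ratio of initial lymph-node to initial blood
  leukemic burden, `B_LN0 / B_bl0`; it converts lymph-node fold-changes into
  blood fold-change units.
* `lam_i`, `mu_i` (1/d) — constant renewal and first-order death of each
  T/NK population in blood.
* `sig_i` (dimensionless) — coupling of each T population's lymph-node
  influx to the leukemic efflux flux `F_out * B_LN`. The influx is
  proportional to the lymph-node leukemic burden, and scales with the exit
  rate so that opening the lymph-node exit at treatment onset drives the
  observed transient T-cell rise.

Assumptions worth making explicit: renewal is a zeroth-order source
(constant renewal plus linear death is the minimal standard form and keeps
the system linear); there is no direct interaction term between blood
leukemic B cells and T cells (blood dynamics of the two arms are coupled
only through the lymph-node compartment); treatment effect is a step change
already folded into the rates (no pharmacokinetics); lymph-node death is
folded into the net rates.

Because the system is linear and lower-triangular, every compartment has an
explicit solution (a two-exponential expression, with a `t*exp(-mu t)` limit
branch when two rates coincide within a relative gap of 1e-8). The closed
form is the production solver everywhere in the package; the LSODA-based
numerical integrator is kept behind the same interface for future nonlinear
variants and is cross-checked against the closed form to 1e-6 relative error
in the test-suite.

## The synthetic cohort generator

No patient-level data are distributed, so the generator is the ground-truth
source for every downstream test. It emulates the cohort-1 design: 28 tHL +
13 pHL patients; blood measurements at months 0, 1, 2, 3, 6, 12, 18, 24 and
lymph-node (MRI-volume fold-change) measurements at months 1, 12, 24, with
one month fixed at 30.4375 days; visit-level missingness (default 5%, never
at month 0).

Individual parameters follow the log-normal mixed-effects model
`log theta_i = log theta_pop + beta * 1{pHL} + eta_i`, `eta_i ~ N(0, Omega)`.
Defaults: random-effect SD 0.3 on the log scale for every parameter
(moderate inter-patient spread that keeps recovery feasible at n of about
40), equicorrelated blocks over the T-cell death rates and over
(`f_in`, `F_out`) with rho = 0.5, and group coefficients
`beta = {F_out: ln 44, f_in: -ln 5, mu_4: ln 1.3}` — the reported
multiplicative contrasts between the pHL and tHL groups. Observation error
is `y = m + (a + b m) * eps` per variable; the packaged scenario uses 15%
proportional error on the model compartments and 10% on the ALC. Values
below a positive floor (1e-4 fold-change) are redrawn rather than truncated,
so low-signal variables are not biased; the floor sits far below every
modelled signal.

The ALC is assembled in G/L from per-patient baseline counts (log-normal
around 40 G/L leukemic B, 1 / 0.6 / 0.3 G/L CD4 / CD8 / NK; Tregs are a CD4
subset and are not added again), multiplied by the fold-change trajectories.
Classification therefore sees a realistic, B-cell-dominated composite.

### Reference kinetics

The study's parameter tables are not available, so the tHL reference fixed
effects are the package's own choice, set to reproduce the qualitative
signatures the clinical data show: a brief shallow blood lymphocytosis
resolving below baseline by month 3 in tHL; a pronounced blood peak (about
4x) around month 1 in pHL, still about 1.8x baseline at month 3 and resolved
by month 24; T-cell rises of several tens of percent at month 1 in pHL,
settling below baseline; slow lymph-node shrinkage in tHL, fast emptying in
pHL. The values are

    f_in = 4.0e-4 /d   F_out = 1.7e-3 /d   mu_B = 0.015 /d   kappa = 5
    mu_4 = 0.020  mu_8 = 0.018  mu_NK = 0.025  mu_reg = 0.022  (/d)
    lam_i = 0.8 * mu_i            sig_4/8/NK/reg = 1.5 / 1.2 / 2.5 / 1.5

A structural fact about this design discovered during its analysis: the
three clinical constraints (pHL still above baseline at month 3, tHL below
baseline at month 3, both with shared `mu_B` and `kappa`) force the tHL exit
rate to be so small that the lymph-node decay is well under 70% complete at
month 24. With imaging only at months 1, 12 and 24, `(f_in, F_out)` then
form a genuine likelihood ridge on the tHL side: maximum-likelihood
estimates of `f_in` can sit 20-40% from the generating value at essentially
identical likelihood. This is a property of the study design, not of the
estimator, and it is why the recovery test documents `f_in` separately (all
other fixed effects recover with median error well inside 15% at n = 41).

What the generator does *not* emulate: informative dropout, visit-date
jitter (tables carry exact days, so real data with jittered dates ingest
unchanged), assay changes over time, or model misspecification — passing
recovery tests therefore show estimator correctness under the assumed model,
not robustness to model error.

## Group-mean fitting and profile likelihood

`fit_group_means` maximises a Gaussian likelihood on log-transformed means
and predictions (the multiplicative-error analogue of least squares), with
each variable's error SD profiled out analytically. Optimisation runs in
log-parameter space (bounds 1e-6..1e3 per day): each start first runs a
trust-region Gauss-Newton pass on the stacked log-residual vector — far more
reliable on sums-of-exponentials than quasi-Newton on the scalar objective —
then polishes with L-BFGS-B on the profiled likelihood; restarts perturb the
initial values log-uniformly. Non-identifiable parameters are flagged by a
local curvature probe and by bound contact.

Profile-likelihood intervals re-optimise all other parameters on a grid for
the profiled one and cut at `min -2LL + chi2_1(0.95) = 3.841`. The default
grid is curvature-matched: its span and resolution are derived from the
local second difference at the optimum so that the chi-square crossing is
resolved finely (a fixed coarse grid systematically narrows the interval
through interpolation error). AICc is
`-2LL + 2k + 2k(k+1)/(n-k-1)`, reported as NaN when `n <= k+1`.

## SAEM population estimation

The population model is the same log-normal individual model the generator
uses, with the group covariate additive on the log scale and `Omega`
restricted to declared correlation blocks. Parameters excluded from the
random-effect set are pinned with a small frozen log-variance (0.05^2)
instead of exactly zero, which keeps the sampling kernel and the M-step
uniform across parameters.

The E-step runs three Metropolis-Hastings kernels per iteration on each
patient's log-parameters: (1) an independent proposal from the current
population distribution; (2) a joint random walk with covariance
proportional to the current `Omega`; (3) a per-patient adaptive-covariance
random walk (Haario-style, running mean/covariance of the chain) plus
componentwise walks over the parameters that can influence the observed
variables. All step sizes adapt toward an acceptance rate of 0.3. The
adaptive and joint kernels matter: several parameter pairs (production and
exit rate; each T population's renewal, influx and death) are strongly
correlated in the per-patient posterior, and componentwise moves alone mix
too slowly along those ridges for the stochastic approximation to converge.

Sufficient statistics are smoothed with step 1 during exploration and
`(k - k_explore)^-0.7` during smoothing (defaults 300 + 200 iterations, one
chain, three transitions per kernel). The M-step is exact: a generalised
least-squares update for the fixed effects and group coefficients (solving
the coupled normal equations under the current `Omega`), the block-restricted
empirical covariance for `Omega`, and moment updates for the error
parameters — with the relative-residual statistic smoothed directly for the
proportional model (deriving it from separately smoothed numerator and
denominator is Jensen-biased) and a two-parameter numerical minimisation for
the combined model. During exploration a simulated-annealing floor (0.95 per
iteration) keeps the error and random-effect variances from collapsing
prematurely; it can be switched off.

Post-fit quantities:

* **Empirical Bayes estimates** — per-patient MAP of the log-parameters by
  L-BFGS-B, falling back to the population mean when data carry no
  information (full shrinkage).
* **Marginal likelihood** — per-patient importance sampling with a
  multivariate t (5 df) proposal centred at the posterior mean with 1.3x the
  posterior covariance from a short MH run. The integral is restricted to
  the parameters the likelihood can see (plus any random effects coupled to
  them through `Omega`); the remaining dimensions integrate out exactly, and
  carrying them in the sampler only adds weight noise — restricting them cut
  the Monte-Carlo SE by an order of magnitude on submodels. A Monte-Carlo SE
  and an effective-sample-size warning are reported.
* **Standard errors** — Louis' identity over MH samples at the final
  estimates (complete-data information minus the posterior score
  covariance), or central differences of the importance-sampled
  log-likelihood with common random numbers as a cross-check. At small n the
  Wald test inherits the usual mild anticonservatism of ML variance
  estimates; the calibration test budgets for it.

## Automatic model building

The builder iterates three move classes from each initial configuration:
per-variable error-model swaps, group-covariate addition/removal (screened
first by a Wald test of group on the EBE log-values, threshold 0.05), and
correlation-block proposals (screened by pairwise EBE correlations,
|r| > 0.5). A move is accepted only if the corrected BIC improves:

    BICc = -2LL + k_subject * log(n_subjects) + k_obs * log(n_obs)

with subject-level parameters (fixed effects, group coefficients, free
`Omega` entries) penalised by the subject count and observation-level
(error) parameters by the observation count. The final model keeps the
features common to every configuration's selection (consensus by
intersection), and a multi-start pass over perturbed initial fixed effects
reports per-parameter spreads with a 10% practical-identifiability verdict.

Shrinkage attenuates EBE correlations, so the correlation screen only fires
when the individual parameters are reasonably identified; the packaged
consistency study therefore uses steep T-cell kinetics. Five packaged
initial configurations span constant/proportional errors, full/partial
random-effect sets and with/without the group covariate.

## Statistical tests

Mann-Whitney U (exact enumeration of the permutation null over average ranks
up to combined n = 14; tie-corrected, continuity-corrected normal
approximation above), paired Student t, Pearson chi-square on 2x2 tables
(Yates correction available, off by default), and the Wald z test. An
exhaustive enumeration shows the exact and normal-approximation two-tailed
p-values agree within 0.05 for every tie-free design with at least three
observations per arm; the 2+2 and 2+3 designs exceed the band (worst gaps
0.088 and 0.051) and the exact mode is the default at those sizes.

## Numerical choices and problem sizes

* ODE tolerances: integrator rtol 1e-10 / atol 1e-12 (the closed form is
  exact and is what production code paths use).
* Mean-fit optimiser: Gauss-Newton stage capped at 500 residual evaluations,
  L-BFGS-B polish ftol 1e-14.
* SAEM harness sizes in the shipped studies were chosen for convergence at
  desk scale: the recovery study uses 600 + 500 iterations (the smoothing
  trace drifts < 1% over its last 50 iterations there), the calibration
  study 100 + 200 iterations on a two-variable B-cell submodel with 100 null
  replicates, and the builder studies 80-120 + 60-100 iterations on
  submodels.
* Determinism: every stochastic routine takes an explicit seed and is
  byte-reproducible from it; estimates are invariant to observation-row
  order because patients and times are canonically sorted at ingestion.

## Known limitations

* The tHL-side `(f_in, F_out)` ridge above: with the study's sparse imaging
  schedule the lymph-node production rate is structurally soft; profile
  intervals for it are wide and point estimates should not be
  over-interpreted. This mirrors what any estimator would face on the real
  design.
* BICc-based discrimination between constant and proportional error weakens
  when smooth individual curves let random effects absorb heteroscedasticity
  (few observations per patient, no replicates); the builder studies use
  designs where the residual structure is actually visible.
* The Wald test at n of about 20 is mildly anticonservative (ML variance
  estimates, no small-sample correction), consistent with its calibration
  band.
* Between-occasion variability, time-varying covariates and dropout
  mechanisms are out of scope.
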