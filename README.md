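# cllkin — lymphocyte kinetics under BTK inhibition in CLL

Ibrutinib, a Bruton-tyrosine-kinase inhibitor used in chronic lymphocytic
leukemia (CLL), makes leukemic B cells leave the lymph nodes and surge
transiently into blood. Patients divide into two response groups by their
absolute lymphocyte count (ALC): **tHL** (transient hyperlymphocytosis,
ALC at month 3 below its pre-treatment value) and **pHL** (prolonged,
ALC M3 > ALC M0). `cllkin` is a Python library for analysing this process
end to end, aimed at pharmacometricians and quantitative clinicians:

* a six-compartment linear ODE model of leukemic B cells (lymph node and
  blood) and blood CD4/CD8/NK/Treg cells, in fold-changes of baseline:

  ```
  dB_LN/dt = f_in − F_out·B_LN
  dB_bl/dt = κ·F_out·B_LN − μ_B·B_bl
  dT_i/dt  = λ_i + σ_i·F_out·B_LN − μ_i·T_i        i ∈ {4, 8, NK, reg}
  ```

  with an exact closed-form solver (the system is linear) cross-checked
  against numerical integration;
* a virtual-cohort generator with log-normal inter-patient variability
  (`log θ_i = log θ_pop + β·1{pHL} + η_i`, `η_i ~ N(0, Ω)`), group
  covariates, per-variable observation error and the study's visit schedule;
* tHL/pHL classification, percent-change summaries, the four-factor BALL
  prognostic score, and the elementary tests (exact/normal Mann-Whitney,
  paired t, chi-square, Wald);
* maximum-likelihood fitting of group-mean time courses with corrected AIC
  and profile-likelihood confidence intervals;
* a SAEM (stochastic-approximation EM) estimator for the nonlinear
  mixed-effects model — covariate coefficients, correlated random-effect
  blocks, per-variable error models, importance-sampled marginal likelihood,
  Louis-identity standard errors and covariate Wald tests;
* an automatic statistical-model builder (error model, covariates,
  correlation blocks) under the corrected BIC, with consensus over multiple
  initial configurations and multi-start identifiability checks.

## A worked example

```python
import numpy as np
from cllkin import (emulate_study_scenario, generate_cohort,
                    NLMEModelSpec, SAEMSettings, saem_fit,
                    estimate_standard_errors, wald_test_covariate)
from cllkin.dynamics import PARAM_NAMES

pop, design = emulate_study_scenario(seed=11)      # 28 tHL + 13 pHL patients
obs, cov, truth = generate_cohort(pop, design)
groups = dict(zip(truth.patient_id, truth.group))

spec = NLMEModelSpec(
    random_effects=tuple(PARAM_NAMES),
    covariates=("f_in", "F_out", "mu_4"),
    correlation_blocks=(("mu_4", "mu_8", "mu_NK", "mu_reg"),
                        ("f_in", "F_out")),
    error_models={v: "proportional"
                  for v in ("B_LN", "B_bl", "T4", "T8", "TNK", "Treg")})
fit = saem_fit(obs, spec, SAEMSettings(k_explore=300, k_smooth=200, seed=1),
               pop, groups=groups)
estimate_standard_errors(fit)
for name in spec.covariates:
    r = wald_test_covariate(fit, name)
    print(f"{name:6s} group ratio x{np.exp(fit.beta[name]):6.2f}   "
          f"Wald p = {r.p_value:.2e}")
```

prints (exactly, for these seeds):

```
f_in   group ratio x  0.23   Wald p = 2.55e-23
F_out  group ratio x 41.42   Wald p = 0.00e+00
mu_4   group ratio x  1.30   Wald p = 3.52e-06
```

Read: the prolonged-lymphocytosis group empties its lymph nodes ~41 times
faster (generating value 44), produces leukemic cells about 4 times slower
in the nodes (x0.23; generating value 1/5), and loses CD4 cells 1.3 times
faster — each group coefficient tested against zero by a Wald test on its
log-scale standard error. The `examples/` directory holds one short script
per capability (simulation, classification, group-mean fitting with profile
intervals, population estimation, automatic model building).

A thin CLI wraps the same library for shell use:

```
cllkin simulate --params params.txt --out trajectory.csv
cllkin run --config pipeline.yaml        # classify → summarise → fit → report
```

## Package layout

```
src/cllkin/
  dynamics.py   compartment model, closed form, integrator, steady state
  cohort.py     population model, virtual-cohort generator, packaged scenario
  analysis.py   tHL/pHL classification, percent change, BALL score, summaries
  stats.py      Mann-Whitney (exact + normal), paired t, chi-square, Wald
  meanfit.py    group-mean ML fits, AICc, profile-likelihood intervals
  nlme.py       SAEM, EBEs, importance-sampled likelihood, standard errors
  builder.py    BICc model building, consensus, multi-start identifiability
  io.py         cohort CSV schema, config parsing
  pipeline.py   end-to-end driver with run manifest
  cli.py        command-line interface
```

`docs/methods.md` documents the model, the estimator internals, the default
parameter choices and the known limitations.
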