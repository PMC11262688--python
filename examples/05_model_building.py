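"""Automatic statistical-model building on a small virtual cohort: the
builder compares error models, screens the group covariate on each
parameter's empirical-Bayes estimates and accepts moves only when the
corrected BIC improves."""

import numpy as np

from cllkin.builder import BuildConfig, build_model
from cllkin.cohort import (CohortDesign, ErrorModel, PopulationModel,
                           generate_cohort, reference_parameters)
from cllkin.nlme import NLMEModelSpec, SAEMSettings, make_ode_problem

B_VARS = ("B_LN", "B_bl")
B_PARAMS = ("f_in", "F_out", "mu_B", "kappa")

theta = reference_parameters()
pop = PopulationModel.from_sds(
    theta, {p: 0.2 for p in B_PARAMS},
    beta={"F_out": float(np.log(44.0))},
    error_models={v: ErrorModel("proportional", b=0.15)
                  for v in ("B_bl", "T4", "T8", "TNK", "Treg", "B_LN", "ALC")})
design = CohortDesign(n_thl=12, n_phl=6, missing_rate=0.0, seed=5)
obs, _, truth = generate_cohort(pop, design)
groups = dict(zip(truth.patient_id, truth.group))
problem = make_ode_problem(obs, groups, variables=B_VARS)

spec0 = NLMEModelSpec(random_effects=B_PARAMS, covariates=(),
                      error_models={v: "proportional" for v in B_VARS})
config = BuildConfig(initial_specs=[spec0], candidate_covariates=B_PARAMS,
                     candidate_blocks=(("f_in", "F_out"),),
                     max_iterations=2, n_importance=300, seed=3)
final, report = build_model(
    problem, config, SAEMSettings(k_explore=80, k_smooth=60, mh_steps=2,
                                  seed=2), pop)

print(report.to_string(index=False))
print("\nselected covariates:", final.covariates or "(none)")
print("selected error models:", dict(final.error_models))
print("\nThe cohort was generated with a 44x group contrast on the efflux "
      "rate only, so the builder should add the group covariate on F_out "
      "and nothing else (each accepted move lowers the corrected BIC).")
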