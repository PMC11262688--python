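"""Population (mixed-effects) estimation on a virtual cohort: SAEM with a
group covariate on the lymph-node production and exit rates and the CD4
death rate, followed by Wald tests of the group coefficients.

Uses moderately reduced iteration counts so the example runs in ~15 s.
"""

import numpy as np

from cllkin.cohort import emulate_study_scenario, generate_cohort
from cllkin.dynamics import PARAM_NAMES
from cllkin.nlme import (NLMEModelSpec, SAEMSettings, estimate_standard_errors,
                         saem_fit, wald_test_covariate)

pop, design = emulate_study_scenario(seed=11)
obs, _, truth = generate_cohort(pop, design)
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

print(f"{'parameter':>8} {'estimate':>10} {'group effect':>13} {'Wald p':>10}")
for nm in ("f_in", "F_out", "mu_B", "kappa", "mu_4"):
    beta = fit.beta.get(nm)
    p = wald_test_covariate(fit, nm).p_value if nm in spec.covariates else None
    print(f"{nm:>8} {fit.theta_pop[nm]:>10.4g} "
          f"{'x%.2f' % np.exp(beta) if beta is not None else '-':>13} "
          f"{('%.2e' % p) if p is not None else '-':>10}")

print("\n'x44' on F_out means the prolonged-lymphocytosis group empties its "
      "lymph nodes ~44 times faster; the Wald p-value tests that the group "
      "coefficient differs from zero.")
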