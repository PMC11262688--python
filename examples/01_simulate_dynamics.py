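"""Simulate the six-compartment lymphocyte model for a transient (tHL) and a
prolonged (pHL) hyperlymphocytosis patient and print the blood leukemic
B-cell fold-changes at key visits.

The pHL parameter set differs from tHL by the reported group contrasts: a
44x higher lymph-node exit rate, a 5x lower lymph-node production rate and a
1.3x higher CD4 death rate.
"""

import numpy as np

from cllkin import KineticParameters, closed_form, percent_change_curve
from cllkin.cohort import DAYS_PER_MONTH, reference_parameters

months = [0, 1, 2, 3, 6, 12, 24]
times = np.array([m * DAYS_PER_MONTH for m in months])

thl = reference_parameters()
phl = dict(thl)
phl["F_out"] *= 44.0
phl["f_in"] /= 5.0
phl["mu_4"] *= 1.3

print(f"{'month':>6} {'tHL B_bl':>10} {'pHL B_bl':>10} {'pHL T4 %chg':>12}")
traj_t = closed_form(KineticParameters(**thl), times)
traj_p = closed_form(KineticParameters(**phl), times)
pct_p = percent_change_curve(traj_p)
for i, m in enumerate(months):
    print(f"{m:>6} {traj_t.compartment('B_bl')[i]:>10.2f} "
          f"{traj_p.compartment('B_bl')[i]:>10.2f} "
          f"{pct_p.compartment('T4')[i]:>+11.0f}%")

print("\nThe pHL blood leukemic burden peaks around month 1-2 and is still "
      "above its pre-treatment level at month 3 (the pHL definition), while "
      "the tHL burden declines; pHL CD4 counts rise transiently as T cells "
      "are flushed out of the emptying lymph nodes.")
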