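import numpy as np
import pytest

from cllkin.cohort import (CohortDesign, ErrorModel, PopulationModel,
                           reference_parameters)
from cllkin.dynamics import PARAM_NAMES


@pytest.fixture
def ref_theta():
    return reference_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_valid_params(rng):
    """Random kinetic parameter dict with realistic magnitudes."""
    draw = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    d = {
        "f_in": draw(1e-5, 1e-2), "F_out": draw(1e-4, 0.5),
        "mu_B": draw(1e-3, 0.2), "kappa": draw(0.5, 20.0),
    }
    for s in ("4", "8", "NK", "reg"):
        d[f"mu_{s}"] = draw(1e-3, 0.2)
        d[f"lam_{s}"] = draw(1e-4, 0.1)
        d[f"sig_{s}"] = draw(0.01, 3.0)
    return d


@pytest.fixture
def small_population(ref_theta):
    """Small two-group population with mild variability and noise."""
    errors = {v: ErrorModel("proportional", b=0.1)
              for v in ("B_bl", "T4", "T8", "TNK", "Treg", "B_LN")}
    errors["ALC"] = ErrorModel("proportional", b=0.1)
    return PopulationModel.from_sds(
        ref_theta, {n: 0.2 for n in PARAM_NAMES},
        beta={"F_out": float(np.log(44.0))},
        error_models=errors)


@pytest.fixture
def small_design():
    return CohortDesign(n_thl=8, n_phl=5, missing_rate=0.0, seed=7)
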