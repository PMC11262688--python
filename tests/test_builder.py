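"""Automatic model building: BICc, error-model selection, covariate and
correlation moves, consensus and multi-start identifiability."""

import numpy as np
import pytest

from cllkin.builder import (BuildConfig, bicc, build_model, consensus_spec,
                            default_initial_specs, multi_start, replace_spec,
                            select_error_model)
from cllkin.cohort import (CohortDesign, ErrorModel, PopulationModel,
                           generate_cohort, reference_parameters)
from cllkin.exceptions import ValidationError
from cllkin.nlme import NLMEModelSpec, SAEMSettings, make_ode_problem

FAST = SAEMSettings(k_explore=80, k_smooth=60, mh_steps=2, seed=2)
B_VARS = ("B_LN", "B_bl")
B_PARAMS = ("f_in", "F_out", "mu_B", "kappa")


def b_cell_problem(b=0.2, kind="proportional", n=16, seed=4, sds=0.25,
                   beta=None, a=None, theta=None):
    theta = theta or reference_parameters()
    if kind == "proportional":
        em = {v: ErrorModel("proportional", b=b) for v in
              ("B_bl", "T4", "T8", "TNK", "Treg", "B_LN", "ALC")}
    else:
        em = {v: ErrorModel("constant", a=a) for v in
              ("B_bl", "T4", "T8", "TNK", "Treg", "B_LN", "ALC")}
    pop = PopulationModel.from_sds(theta, {p: sds for p in B_PARAMS},
                                   beta=beta or {}, error_models=em)
    design = CohortDesign(n_thl=n - n // 3, n_phl=n // 3, missing_rate=0.0,
                          seed=seed)
    obs, _, truth = generate_cohort(pop, design)
    groups = dict(zip(truth.patient_id, truth.group))
    return make_ode_problem(obs, groups, variables=B_VARS), pop


class TestBicc:
    def test_penalty_formula(self):
        assert bicc(0.0, int(np.e**2) + 1, 100, 2, 0) == pytest.approx(
            2 * np.log(int(np.e**2) + 1))
        # illustrative continuous subject count
        assert bicc(0.0, np.e**2, 10, 2, 0) == pytest.approx(4.0)

    def test_reduces_to_subject_bic_without_error_params(self):
        assert bicc(5.0, 30, 200, 3, 0) == pytest.approx(5.0 + 3 * np.log(30))

    def test_monotone_in_parameter_counts(self):
        base = bicc(10.0, 30, 200, 3, 2)
        assert bicc(10.0, 30, 200, 4, 2) > base
        assert bicc(10.0, 30, 200, 3, 3) > base
        with pytest.raises(ValidationError):
            bicc(0.0, 0, 10, 1, 1)


class TestErrorModelSelection:
    def test_proportional_generator_selects_proportional(self):
        prob, pop = b_cell_problem(b=0.2, kind="proportional")
        spec = NLMEModelSpec(random_effects=B_PARAMS,
                             error_models={v: "constant" for v in B_VARS})
        chosen, rows = select_error_model(prob, spec, FAST, pop, seed=1)
        assert chosen["B_bl"] == "proportional"

    def test_constant_generator_selects_constant(self):
        prob, pop = b_cell_problem(kind="constant", a=0.12, n=21, sds=0.2)
        spec = NLMEModelSpec(random_effects=B_PARAMS,
                             error_models={v: "proportional" for v in B_VARS})
        chosen, rows = select_error_model(prob, spec, FAST, pop, seed=1)
        assert chosen["B_bl"] == "constant"


class TestConsensus:
    def test_intersection_is_subset_of_each_configuration(self):
        a = NLMEModelSpec(("f_in", "F_out"), ("f_in", "F_out"),
                          (("f_in", "F_out"),), {"B_bl": "proportional"})
        b = NLMEModelSpec(("f_in", "F_out", "mu_B"), ("F_out",),
                          (), {"B_bl": "proportional"})
        final = consensus_spec([a, b])
        assert set(final.covariates) <= set(a.covariates)
        assert set(final.covariates) <= set(b.covariates)
        assert final.covariates == ("F_out",)
        assert final.correlation_blocks == ()

    def test_default_initial_specs_structure(self):
        specs = default_initial_specs(B_VARS)
        assert len(specs) == 5
        kinds = {s.error_models["B_bl"] for s in specs}
        assert kinds == {"constant", "proportional"}
        assert any(s.covariates for s in specs)
        assert any(not s.covariates for s in specs)


class TestBuildModel:
    def test_strong_group_effect_recovered_and_bicc_monotone(self):
        prob, pop = b_cell_problem(
            b=0.15, sds=0.2, n=18, seed=6,
            beta={"F_out": float(np.log(44.0))})
        spec0 = NLMEModelSpec(random_effects=B_PARAMS, covariates=(),
                              error_models={v: "proportional" for v in B_VARS})
        config = BuildConfig(initial_specs=[spec0],
                             candidate_covariates=B_PARAMS,
                             candidate_blocks=(("f_in", "F_out"),),
                             max_iterations=2, n_importance=300, seed=3)
        final, report = build_model(prob, config, FAST, pop)
        assert "F_out" in final.covariates
        acc = report[report.accepted & report.bicc.notna()]
        for cfg, sub in acc.groupby("config"):
            assert (np.diff(sub.bicc.to_numpy()) < 1e-9).all()

    def test_null_generator_selects_no_covariates(self):
        prob, pop = b_cell_problem(b=0.15, sds=0.2, n=18, seed=8)
        spec0 = NLMEModelSpec(random_effects=B_PARAMS, covariates=(),
                              error_models={v: "proportional" for v in B_VARS})
        config = BuildConfig(initial_specs=[spec0],
                             candidate_covariates=B_PARAMS,
                             candidate_blocks=(), max_iterations=1,
                             n_importance=300, seed=3)
        final, report = build_model(prob, config, FAST, pop)
        assert final.covariates == ()


class TestMultiStart:
    def test_degenerate_data_all_starts_agree(self):
        """No inter-patient variability and low noise: a single optimum, so
        every perturbed start lands on it (residual spread is the SAEM
        Monte-Carlo jitter)."""
        theta = reference_parameters()
        # fast lymph-node drainage plus dense LN sampling: every B-cell rate
        # is sharply identified, leaving a single optimum
        theta.update(F_out=0.01, f_in=2e-3)
        em = {v: ErrorModel("proportional", b=0.02)
              for v in ("B_bl", "T4", "T8", "TNK", "Treg", "B_LN", "ALC")}
        pop = PopulationModel.from_sds(theta, {p: 1e-6 for p in B_PARAMS},
                                       error_models=em)
        design = CohortDesign(n_thl=7, n_phl=3, missing_rate=0.0, seed=9)
        design.ln_visits = design.blood_visits
        obs, _, truth = generate_cohort(pop, design)
        groups = dict(zip(truth.patient_id, truth.group))
        prob = make_ode_problem(obs, groups, variables=B_VARS)
        spec = NLMEModelSpec(random_effects=B_PARAMS,
                             error_models={v: "proportional" for v in B_VARS})
        rep = multi_start(prob, spec, pop, n_starts=3,
                          perturbation_factor=2.0,
                          settings=SAEMSettings(k_explore=150, k_smooth=250,
                                                mh_steps=2, seed=2))
        spread = rep.set_index("parameter").spread
        assert (spread[list(B_PARAMS)] < 0.03).all()
        assert rep.set_index("parameter").identifiable[list(B_PARAMS)].all()

    def test_unobserved_compartment_parameters_flagged(self):
        prob, pop = b_cell_problem(b=0.15, sds=0.25, n=12, seed=10)
        # T-cell parameters receive random effects but no T data exist
        spec = NLMEModelSpec(
            random_effects=B_PARAMS + ("mu_4", "lam_4", "sig_4"),
            error_models={v: "proportional" for v in B_VARS})
        rep = multi_start(prob, spec, pop, n_starts=3,
                          perturbation_factor=4.0, settings=FAST)
        rep = rep.set_index("parameter")
        assert not rep.loc["sig_4", "identifiable"]
        assert not rep.loc["lam_4", "identifiable"]

    def test_requires_two_starts(self):
        prob, pop = b_cell_problem()
        spec = NLMEModelSpec(random_effects=B_PARAMS,
                             error_models={v: "proportional" for v in B_VARS})
        with pytest.raises(ValidationError):
            multi_start(prob, spec, pop, n_starts=1)
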