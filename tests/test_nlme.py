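"""SAEM estimator checked against the conjugate one-way random-effects
model, degenerate noiseless limits, determinism and post-fit quantities."""

import numpy as np
import pandas as pd
import pytest

from cllkin.cohort import (CohortDesign, ErrorModel, PopulationModel,
                           generate_cohort, reference_parameters)
from cllkin.dynamics import PARAM_NAMES
from cllkin.exceptions import ValidationError
from cllkin.nlme import (FROZEN_VARIANCE, NLMEModelSpec, SAEMProblem,
                         SAEMSettings, conditional_modes,
                         estimate_loglikelihood, estimate_standard_errors,
                         make_ode_problem, saem_fit, wald_test_covariate)


class InitConst:
    """Minimal init object for generic SAEM problems."""

    def __init__(self, theta_pop, beta=None, error_models=None):
        self.theta_pop = theta_pop
        self.beta = beta or {}
        self.error_models = error_models or {}


def one_way_problem(n=50, j=4, mu=np.log(2.0), omega=0.3, sigma=0.25,
                    seed=1, group=None):
    """Balanced one-way model y_ij = phi_i + eps via a log structural map."""
    rng = np.random.default_rng(seed)
    g = np.zeros(n) if group is None else group
    phi = mu + omega * rng.standard_normal(n)
    y = phi[:, None] + sigma * rng.standard_normal((n, j))
    prob = SAEMProblem(y[:, None, :], g, np.arange(j, dtype=float),
                       [f"P{i:03d}" for i in range(n)], ["Y"], ["theta"],
                       lambda th: np.repeat(np.log(th)[:, :1][:, :, None],
                                            j, axis=2))
    return prob, y


def one_way_mle(y):
    """Closed-form balanced one-way random-effects Gaussian MLE."""
    n, j = y.shape
    ybar_i = y.mean(axis=1)
    mu = y.mean()
    ssw = ((y - ybar_i[:, None]) ** 2).sum()
    sigma2 = ssw / (n * (j - 1))
    tau = ((ybar_i - mu) ** 2).mean()
    omega2 = tau - sigma2 / j
    return mu, omega2, sigma2, tau


def one_way_minus2ll(y, mu, omega2, sigma2):
    n, j = y.shape
    cov = sigma2 * np.eye(j) + omega2 * np.ones((j, j))
    sign, logdet = np.linalg.slogdet(cov)
    w = np.linalg.inv(cov)
    d = y - mu
    quad = np.einsum("nj,jk,nk->n", d, w, d)
    return float(n * (j * np.log(2 * np.pi) + logdet) + quad.sum())


SPEC_1D = NLMEModelSpec(random_effects=("theta",), covariates=(),
                        correlation_blocks=(), error_models={"Y": "constant"})


@pytest.fixture(scope="module")
def conjugate_fit():
    prob, y = one_way_problem()
    fit = saem_fit(prob, SPEC_1D,
                   SAEMSettings(k_explore=200, k_smooth=400, seed=3),
                   InitConst({"theta": 1.0}))
    return prob, y, fit


class TestConjugateOracle:
    def test_estimates_match_closed_form_mle(self, conjugate_fit):
        prob, y, fit = conjugate_fit
        mu, omega2, sigma2, _ = one_way_mle(y)
        assert np.exp(fit.mu_vector()[0]) == pytest.approx(np.exp(mu), rel=0.02)
        assert fit.omega[0, 0] == pytest.approx(omega2, rel=0.02)
        assert fit.error_models["Y"].a ** 2 == pytest.approx(sigma2, rel=0.02)

    def test_importance_sampled_likelihood_matches_analytic(self, conjugate_fit):
        prob, y, fit = conjugate_fit
        m2, mc_se = estimate_loglikelihood(fit, n_importance=1000, seed=5)
        analytic = one_way_minus2ll(y, fit.mu_vector()[0], fit.omega[0, 0],
                                    fit.error_models["Y"].a ** 2)
        assert abs(m2 - analytic) <= 3 * mc_se

    def test_grand_mean_se_matches_closed_form(self, conjugate_fit):
        prob, y, fit = conjugate_fit
        n, j = y.shape
        _, _, _, tau = one_way_mle(y)
        ses = estimate_standard_errors(fit, method="louis")
        se_ref = np.sqrt((fit.omega[0, 0] + fit.error_models["Y"].a ** 2 / j)
                         / n)
        assert ses["log_theta_pop"]["theta"] == pytest.approx(se_ref, rel=0.10)

    def test_se_methods_agree(self, conjugate_fit):
        prob, y, fit = conjugate_fit
        a = estimate_standard_errors(fit, method="louis")
        b = estimate_standard_errors(fit, method="ll_numeric")
        ra = a["log_theta_pop"]["theta"]
        rb = b["log_theta_pop"]["theta"]
        assert abs(ra - rb) / ra < 0.20

    def test_se_shrinks_with_sample_size(self):
        ses = {}
        for n in (40, 160):
            prob, y = one_way_problem(n=n, seed=9)
            fit = saem_fit(prob, SPEC_1D,
                           SAEMSettings(k_explore=150, k_smooth=250, seed=3),
                           InitConst({"theta": 1.0}))
            ses[n] = estimate_standard_errors(fit)["log_theta_pop"]["theta"]
        assert ses[40] / ses[160] == pytest.approx(2.0, rel=0.25)

    def test_mc_se_scaling_with_importance_draws(self, conjugate_fit):
        prob, y, fit = conjugate_fit
        _, se_small = estimate_loglikelihood(fit, n_importance=300, seed=11)
        _, se_big = estimate_loglikelihood(fit, n_importance=1200, seed=12)
        assert se_small / se_big == pytest.approx(2.0, rel=0.45)

    def test_single_patient_single_observation_analytic(self):
        prob, y = one_way_problem(n=1, j=1, mu=0.4, omega=0.5, sigma=0.3,
                                  seed=21)
        fit = saem_fit(prob, SPEC_1D,
                       SAEMSettings(k_explore=60, k_smooth=60, seed=3),
                       InitConst({"theta": 1.0}))
        # override with chosen parameters, then check the 1-D integral
        fit.theta_pop = {"theta": float(np.exp(0.4))}
        fit.omega = np.array([[0.25]])
        fit.error_models = {"Y": ErrorModel("constant", a=0.3)}
        m2, mc_se = estimate_loglikelihood(fit, n_importance=4000, seed=5)
        var = 0.25 + 0.09
        analytic = float(np.log(2 * np.pi * var) + (y[0, 0] - 0.4) ** 2 / var)
        assert abs(m2 - analytic) <= max(3 * mc_se, 0.01)


class TestDegenerateAndDeterminism:
    def _tiny_cohort(self, noise=None):
        theta = reference_parameters()
        errors = {} if noise is None else {
            v: ErrorModel("proportional", b=noise)
            for v in ("B_bl", "T4", "T8", "TNK", "Treg", "B_LN", "ALC")}
        pop = PopulationModel(theta_pop=theta, error_models=errors)
        design = CohortDesign(n_thl=8, n_phl=4, missing_rate=0.0, seed=13)
        obs, _, truth = generate_cohort(pop, design)
        groups = dict(zip(truth.patient_id, truth.group))
        return theta, pop, obs, groups

    def test_vanishing_noise_novariability_recovers_theta_pop(self):
        """Omega = 0 and observation error -> 0: the population estimates
        approach the generating values (B-cell submodel; 0.1% noise gives
        ~1% accuracy, 0.01% noise gives <0.5%)."""
        theta = reference_parameters()
        results = {}
        for b in (1e-3, 1e-4):
            em = {v: ErrorModel("proportional", b=b)
                  for v in ("B_bl", "T4", "T8", "TNK", "Treg", "B_LN", "ALC")}
            pop = PopulationModel(theta_pop=theta, error_models=em)
            design = CohortDesign(n_thl=8, n_phl=4, missing_rate=0.0,
                                  seed=13, positive_floor=1e-8)
            obs, _, truth = generate_cohort(pop, design)
            groups = dict(zip(truth.patient_id, truth.group))
            prob = make_ode_problem(obs, groups, variables=("B_LN", "B_bl"))
            spec = NLMEModelSpec(
                random_effects=("f_in", "F_out", "mu_B", "kappa"),
                error_models={"B_LN": "proportional", "B_bl": "proportional"})
            fit = saem_fit(prob, spec,
                           SAEMSettings(k_explore=200, k_smooth=400, seed=5,
                                        annealing=False), pop)
            results[b] = max(abs(fit.theta_pop[n] / theta[n] - 1)
                             for n in ("f_in", "F_out", "mu_B", "kappa"))
        assert results[1e-3] < 0.02
        assert results[1e-4] < 0.005

    def test_seed_determinism_and_row_permutation_invariance(self):
        theta, pop, obs, groups = self._tiny_cohort(noise=0.1)
        spec = NLMEModelSpec(
            random_effects=tuple(PARAM_NAMES), covariates=("F_out",),
            error_models={v: "proportional"
                          for v in ("B_LN", "B_bl", "T4", "T8", "TNK", "Treg")})
        settings = SAEMSettings(k_explore=60, k_smooth=40, seed=17)
        fit1 = saem_fit(obs, spec, settings, pop, groups=groups)
        fit2 = saem_fit(obs, spec, settings, pop, groups=groups)
        assert fit1.theta_pop == fit2.theta_pop
        pd.testing.assert_frame_equal(fit1.trace, fit2.trace)

        shuffled = obs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit3 = saem_fit(shuffled, spec, settings, pop, groups=groups)
        assert fit1.theta_pop == fit3.theta_pop

    def test_trace_length_and_final_omega_psd(self):
        theta, pop, obs, groups = self._tiny_cohort(noise=0.1)
        spec = NLMEModelSpec(
            random_effects=("f_in", "F_out", "mu_B", "kappa"),
            correlation_blocks=(("f_in", "F_out"),),
            error_models={v: "proportional"
                          for v in ("B_LN", "B_bl", "T4", "T8", "TNK", "Treg")})
        settings = SAEMSettings(k_explore=50, k_smooth=30, seed=2)
        fit = saem_fit(obs, spec, settings, pop, groups=groups)
        assert len(fit.trace) == 80
        w = np.linalg.eigvalsh(fit.omega)
        assert w.min() > -1e-12
        # frozen variance for parameters outside the random-effect set
        i = list(PARAM_NAMES).index("mu_4")
        assert fit.omega[i, i] == pytest.approx(FROZEN_VARIANCE)


class TestPostFit:
    def test_ebe_of_data_free_patient_is_population_mean(self):
        prob, y = one_way_problem(n=6, j=3, seed=33)
        prob.y[2] = np.nan
        prob.mask = np.isfinite(prob.y)
        fit = saem_fit(prob, SPEC_1D,
                       SAEMSettings(k_explore=80, k_smooth=80, seed=3),
                       InitConst({"theta": 1.0}))
        ebes = conditional_modes(fit)
        assert ebes.loc["P002", "theta"] == pytest.approx(
            fit.theta_pop["theta"], rel=1e-4)

    def test_ebe_recovers_individuals_in_small_noise_limit(self):
        rng = np.random.default_rng(8)
        n, j = 12, 6
        mu, omega, sigma = np.log(2.0), 0.4, 0.01
        phi = mu + omega * rng.standard_normal(n)
        y = phi[:, None] + sigma * rng.standard_normal((n, j))
        prob = SAEMProblem(y[:, None, :], np.zeros(n),
                           np.arange(j, dtype=float),
                           [f"P{i}" for i in range(n)], ["Y"], ["theta"],
                           lambda th: np.repeat(np.log(th)[:, :1][:, :, None],
                                                j, axis=2))
        fit = saem_fit(prob, SPEC_1D,
                       SAEMSettings(k_explore=150, k_smooth=150, seed=3),
                       InitConst({"theta": 1.0}))
        ebes = conditional_modes(fit)
        assert np.allclose(np.log(ebes["theta"]), phi, atol=0.02)

    def test_wald_requires_covariate_and_standard_errors(self, conjugate_fit):
        prob, y, fit = conjugate_fit
        with pytest.raises(ValidationError):
            wald_test_covariate(fit, "theta")

    def test_wald_on_group_coefficient(self):
        g = np.array([0.0] * 25 + [1.0] * 25)
        prob, y = one_way_problem(n=50, seed=44, group=g)
        # add a genuine group shift
        prob.y[g == 1] += 0.8
        spec = NLMEModelSpec(random_effects=("theta",), covariates=("theta",),
                             error_models={"Y": "constant"})
        fit = saem_fit(prob, spec,
                       SAEMSettings(k_explore=150, k_smooth=250, seed=3),
                       InitConst({"theta": 1.0}))
        estimate_standard_errors(fit)
        r = wald_test_covariate(fit, "theta")
        assert fit.beta["theta"] == pytest.approx(0.8, abs=0.15)
        assert r.p_value < 1e-6


def test_smoothing_phase_trace_is_cauchy_convergent():
    """On the packaged recovery scenario, the smoothing-phase trace settles:
    every fixed effect changes by < 1% over the last 50 iterations."""
    from cllkin.cohort import emulate_study_scenario
    pop, design = emulate_study_scenario(seed=3)
    obs, _, truth = generate_cohort(pop, design)
    groups = dict(zip(truth.patient_id, truth.group))
    spec = NLMEModelSpec(
        random_effects=tuple(PARAM_NAMES), covariates=("f_in", "F_out", "mu_4"),
        correlation_blocks=(("mu_4", "mu_8", "mu_NK", "mu_reg"),
                            ("f_in", "F_out")),
        error_models={v: "proportional"
                      for v in ("B_LN", "B_bl", "T4", "T8", "TNK", "Treg")})
    fit = saem_fit(obs, spec, SAEMSettings(k_explore=300, k_smooth=700,
                                           step_exponent=0.8, seed=5),
                   pop, groups=groups)
    tail = fit.trace.iloc[-50:]
    cols = [c for c in tail.columns if c.startswith("theta_")]
    drift = (tail[cols].iloc[-10:].mean()
             - tail[cols].iloc[:10].mean()).abs() / tail[cols].mean()
    assert drift.max() < 1e-2
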