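"""Nonlinear mixed-effects estimation for the lymphocyte kinetic model.

Individual model (Monolix convention): patient i's log-parameters are

    phi_i = log theta_pop + beta * 1{group_i = pHL} + eta_i,
    eta_i ~ N(0, Omega)

with ``Omega`` restricted to declared correlation blocks.  Observations carry
a per-variable constant, proportional or combined Gaussian error.  Estimation
uses the Stochastic Approximation EM (SAEM) algorithm:

* E-step: Metropolis-Hastings sampling of each patient's ``phi_i`` — an
  independent proposal from the population distribution plus adaptive
  componentwise random walks tuned to a target acceptance rate;
* SA-step: stochastic approximation of the complete-data sufficient
  statistics (step 1 during exploration, ``(k - k_explore)^-alpha`` during
  smoothing);
* M-step: closed-form weighted-Gaussian updates for the fixed effects, the
  group coefficients and the block-restricted ``Omega``; error parameters
  from smoothed residual statistics.

The marginal log-likelihood is recovered afterwards by per-patient importance
sampling with a heavy-tailed proposal centred at the conditional mode, and
standard errors by Louis' identity over Monte-Carlo samples (with a numeric
fallback differentiating the importance-sampled likelihood).

Because the structural system is linear, SAEM evaluates the exact closed-form
solution (vectorised over patients); any callable with the same signature can
be substituted, which the test-suite uses to check SAEM against the conjugate
one-way random-effects model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, logsumexp

from .cohort import ErrorModel, GROUPS
from .dynamics import COMPARTMENTS, PARAM_NAMES, closed_form_states
from .exceptions import NonConvergenceError, ValidationError

#: Frozen log-variance for parameters kept out of the random-effect set;
#: keeps the sampling kernel uniform while pinning those parameters to the
#: population value.
FROZEN_VARIANCE = 0.05**2

_MIN_VARIANCE = 1e-8
_MIN_ERROR_SD = 1e-6


@dataclass(frozen=True)
class NLMEModelSpec:
    """Statistical model structure on top of the kinetic system."""

    random_effects: tuple = tuple(PARAM_NAMES)
    covariates: tuple = ()
    correlation_blocks: tuple = ()
    error_models: Mapping[str, str] = field(
        default_factory=lambda: {v: "proportional" for v in COMPARTMENTS})

    def validate(self, param_names: Sequence[str]):
        names = set(param_names)
        if set(self.random_effects) - names:
            raise ValidationError("random_effects outside parameter names")
        if set(self.covariates) - names:
            raise ValidationError("covariates outside parameter names")
        seen = set()
        for blk in self.correlation_blocks:
            if set(blk) - set(self.random_effects):
                raise ValidationError(f"block {blk} outside random effects")
            if seen & set(blk):
                raise ValidationError("correlation blocks must be disjoint")
            seen |= set(blk)
        for v, kind in self.error_models.items():
            if kind not in ("constant", "proportional", "combined"):
                raise ValidationError(f"unknown error model {kind!r} for {v}")


@dataclass(frozen=True)
class SAEMSettings:
    k_explore: int = 300
    k_smooth: int = 200
    chains: int = 1
    step_exponent: float = 0.7
    mh_steps: int = 3
    target_acceptance: float = 0.3
    annealing: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k_explore < 1 or self.k_smooth < 1:
            raise ValidationError("iteration counts must be >= 1")
        if not (0.5 < self.step_exponent <= 1.0):
            raise ValidationError("step_exponent must be in (0.5, 1]")
        if self.chains < 1:
            raise ValidationError("chains must be >= 1")


class SAEMProblem:
    """Data and structural model packaged for the SAEM engine.

    ``y`` is (N, V, T) with NaN for unobserved entries; ``structural`` maps a
    (M, P) matrix of natural-scale parameters to (M, V, T) predictions.
    """

    def __init__(self, y: np.ndarray, group: np.ndarray, times: np.ndarray,
                 patient_ids: Sequence[str], var_names: Sequence[str],
                 param_names: Sequence[str],
                 structural: Callable[[np.ndarray], np.ndarray],
                 active_params: Sequence[str] | None = None):
        self.y = np.asarray(y, dtype=float)
        self.group = np.asarray(group, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.patient_ids = list(patient_ids)
        self.var_names = tuple(var_names)
        self.param_names = tuple(param_names)
        self.structural = structural
        if self.y.ndim != 3:
            raise ValidationError("y must be (patients, variables, times)")
        self.n, self.n_var, self.n_t = self.y.shape
        if self.group.shape != (self.n,):
            raise ValidationError("group vector length mismatch")
        self.mask = np.isfinite(self.y)
        self.n_obs = int(self.mask.sum())
        # parameters that can influence the observed variables; the sampler
        # skips componentwise updates for the rest (their posterior is the
        # prior, which the other kernels already sample)
        self.active_params = tuple(active_params) if active_params is not None \
            else tuple(param_names)
        if set(self.active_params) - set(self.param_names):
            raise ValidationError("active_params outside parameter names")

    def predictions(self, phi: np.ndarray) -> np.ndarray:
        """(M, P) log-parameters -> (M, V, T) predictions."""
        return self.structural(np.exp(phi))

    def loglik_obs(self, pred: np.ndarray, err_a: np.ndarray,
                   err_b: np.ndarray) -> np.ndarray:
        """Per-row observation log-likelihood for (M, V, T) predictions."""
        sd = err_a[None, :, None] + err_b[None, :, None] * pred
        sd = np.maximum(sd, _MIN_ERROR_SD)
        y = self.y if pred.shape[0] == self.n else np.broadcast_to(
            self.y, pred.shape)
        with np.errstate(invalid="ignore"):
            ll = -0.5 * (np.log(2 * np.pi * sd**2) + ((y - pred) / sd) ** 2)
        return np.where(self.mask if pred.shape[0] == self.n
                        else np.broadcast_to(self.mask, pred.shape),
                        ll, 0.0).sum(axis=(1, 2))


def make_ode_problem(observations: pd.DataFrame, groups: Mapping[str, str],
                     variables: Sequence[str] = COMPARTMENTS) -> SAEMProblem:
    """Build a SAEM problem from a long cohort table (fold-change variables).

    ``groups`` maps patient_id -> tHL/pHL; patients missing from it are
    dropped (e.g., undetermined classifications).
    """
    obs = observations[observations.variable.isin(variables)].copy()
    obs = obs[obs.patient_id.isin(groups)]
    if obs.empty:
        raise ValidationError("no usable observations")
    pids = sorted(obs.patient_id.unique())
    times = np.sort(obs.time_days.unique())
    t_index = {t: i for i, t in enumerate(times)}
    v_index = {v: i for i, v in enumerate(variables)}
    y = np.full((len(pids), len(variables), times.size), np.nan)
    p_index = {p: i for i, p in enumerate(pids)}
    for row in obs.itertuples():
        y[p_index[row.patient_id], v_index[row.variable],
          t_index[row.time_days]] = row.value
    g = np.array([1.0 if groups[p] == "pHL" else 0.0 for p in pids])
    comp_idx = np.array([COMPARTMENTS.index(v) for v in variables])

    def structural(theta: np.ndarray) -> np.ndarray:
        states = closed_form_states(theta, times,
                                    compartments=comp_idx)  # (M, T, 6)
        return states[..., comp_idx].transpose(0, 2, 1)

    active = {"f_in", "F_out"}
    if "B_bl" in variables:
        active |= {"mu_B", "kappa"}
    for v, s in (("T4", "4"), ("T8", "8"), ("TNK", "NK"), ("Treg", "reg")):
        if v in variables:
            active |= {f"mu_{s}", f"lam_{s}", f"sig_{s}"}
    active_t = tuple(n for n in PARAM_NAMES if n in active)
    return SAEMProblem(y, g, times, pids, variables, PARAM_NAMES, structural,
                       active_params=active_t)


@dataclass
class PopulationFit:
    """SAEM estimates plus everything later stages need."""

    theta_pop: dict
    beta: dict
    omega: np.ndarray
    omega_names: tuple
    error_models: dict
    trace: pd.DataFrame
    spec: NLMEModelSpec
    settings: SAEMSettings
    seed: int
    problem: SAEMProblem
    converged: bool = True
    minus2ll: float = float("nan")
    mc_se: float = float("nan")
    ses: dict = field(default_factory=dict)
    ebes: pd.DataFrame | None = None
    events: list = field(default_factory=list)

    # --- parameter bookkeeping -------------------------------------------
    @property
    def param_names(self):
        return self.problem.param_names

    def mu_vector(self) -> np.ndarray:
        return np.array([np.log(self.theta_pop[n]) for n in self.param_names])

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta.get(n, 0.0) for n in self.param_names])

    def k_subject_level(self) -> int:
        """Parameters attached to subjects: fixed effects, covariate
        coefficients and free Omega entries."""
        p = len(self.param_names)
        n_beta = len(self.spec.covariates)
        n_om = len(self.spec.random_effects)
        for blk in self.spec.correlation_blocks:
            n_om += len(blk) * (len(blk) - 1) // 2
        return p + n_beta + n_om

    def k_obs_level(self) -> int:
        return sum(2 if em.kind == "combined" else 1
                   for em in self.error_models.values())


def _structure_mask(param_names, spec: NLMEModelSpec) -> np.ndarray:
    p = len(param_names)
    mask = np.zeros((p, p), dtype=bool)
    np.fill_diagonal(mask, True)
    idx = {n: i for i, n in enumerate(param_names)}
    for blk in spec.correlation_blocks:
        ids = [idx[n] for n in blk]
        for i in ids:
            for j in ids:
                mask[i, j] = True
    return mask


def _restrict_omega(om: np.ndarray, mask: np.ndarray, frozen: np.ndarray,
                    events: list) -> np.ndarray:
    om = np.where(mask, om, 0.0)
    d = np.clip(np.diag(om).copy(), _MIN_VARIANCE, None)
    d[frozen] = FROZEN_VARIANCE
    om[np.diag_indices_from(om)] = d
    om[frozen, :] = np.where(np.eye(len(d), dtype=bool)[frozen, :],
                             om[frozen, :], 0.0)
    om[:, frozen] = om[frozen, :].T
    # guard against indefiniteness introduced by stochastic updates
    w = np.linalg.eigvalsh(om)
    if w.min() < _MIN_VARIANCE * 1e-2 or w.max() / max(w.min(), 1e-300) > 1e12:
        om = om + np.eye(len(d)) * 1e-8
        events.append("omega_regularised")
    return om


def _error_vectors(error_models: Mapping[str, ErrorModel], var_names):
    a = np.array([error_models[v].a for v in var_names])
    b = np.array([error_models[v].b for v in var_names])
    return a, b


def _update_error_models(kinds, var_names, res2, rel2, pred, mask, prev,
                         anneal_floor=None):
    """M-step for the observation error from smoothed residual statistics.

    ``res2``/``rel2`` are the smoothed absolute and relative squared
    residuals (the relative one is smoothed directly rather than derived from
    the two absolute statistics, which would be Jensen-biased)."""
    out = {}
    for j, v in enumerate(var_names):
        m = mask[:, j, :]
        if not m.any():
            out[v] = prev[v]
            continue
        r2 = res2[:, j, :][m]
        mm = np.maximum(pred[:, j, :][m], 1e-12)
        kind = kinds[v]
        if kind == "constant":
            a, b = max(np.sqrt(r2.mean()), _MIN_ERROR_SD), 0.0
        elif kind == "proportional":
            a, b = 0.0, max(np.sqrt(rel2[:, j, :][m].mean()), _MIN_ERROR_SD)
        else:
            def nll(x):
                g = np.maximum(x[0] + x[1] * mm, _MIN_ERROR_SD)
                return float(np.sum(np.log(g) + r2 / (2 * g**2)))
            x0 = np.array([max(prev[v].a, 1e-3), max(prev[v].b, 1e-3)])
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-8})
            a, b = float(max(res.x[0], 0.0)), float(max(res.x[1], 0.0))
            if a + b <= 0:
                a = _MIN_ERROR_SD
        if anneal_floor is not None:
            fa, fb = anneal_floor[v]
            a, b = max(a, fa), max(b, fb)
        out[v] = ErrorModel(kind, a=a if kind != "proportional" else 0.0,
                            b=b if kind != "constant" else 0.0)
    return out


def _mstep_fixed_effects(s1_mean: np.ndarray, group: np.ndarray,
                         omega: np.ndarray, cov_idx: np.ndarray):
    """Exact complete-data GLS update of (mu, beta) given mean log-parameters."""
    n1 = group.sum()
    n0 = len(group) - n1
    phi0 = s1_mean[group == 0].mean(axis=0) if n0 else np.zeros(s1_mean.shape[1])
    phi1 = s1_mean[group == 1].mean(axis=0) if n1 else None
    beta = np.zeros(s1_mean.shape[1])
    if cov_idx.size and n1 and n0:
        d = phi1 - phi0
        w = np.linalg.inv(omega)
        beta[cov_idx] = np.linalg.solve(w[np.ix_(cov_idx, cov_idx)],
                                        (w @ d)[cov_idx])
    if n1 and n0:
        mu = (n0 * phi0 + n1 * (phi1 - beta)) / (n0 + n1)
    elif n1:
        mu = phi1 - beta
    else:
        mu = phi0
    return mu, beta


def saem_fit(observations: pd.DataFrame | SAEMProblem,
             spec: NLMEModelSpec, settings: SAEMSettings,
             init: "PopulationModelLike",
             groups: Mapping[str, str] | None = None) -> PopulationFit:
    """Estimate the population model by SAEM.

    ``observations`` is either a long cohort table (with ``groups`` mapping
    patient ids to tHL/pHL) or a pre-built :class:`SAEMProblem`.  ``init``
    supplies initial ``theta_pop``/``beta``/``error_models`` (a
    :class:`~cllkin.cohort.PopulationModel` works).  Deterministic given
    ``settings.seed``.
    """
    if isinstance(observations, SAEMProblem):
        prob = observations
    else:
        if groups is None:
            raise ValidationError("groups mapping required with a table input")
        prob = make_ode_problem(observations, groups)
    spec.validate(prob.param_names)
    pnames = prob.param_names
    p = len(pnames)
    rng = np.random.default_rng(settings.seed)

    missing = set(pnames) - set(init.theta_pop)
    if missing:
        raise ValidationError(f"init.theta_pop missing {sorted(missing)}")
    mu = np.array([np.log(init.theta_pop[n]) for n in pnames])
    beta = np.array([init.beta.get(n, 0.0) if n in spec.covariates else 0.0
                     for n in pnames])
    cov_idx = np.array([i for i, n in enumerate(pnames)
                        if n in spec.covariates], dtype=int)
    frozen = np.array([n not in spec.random_effects for n in pnames])
    mask_struct = _structure_mask(pnames, spec)
    events: list = []

    omega = np.zeros((p, p))
    init_sds = {}
    init_re = getattr(init, "random_effects", None)
    init_om = getattr(init, "omega", None)
    if init_re is not None and init_om is not None and len(init_re):
        init_sds = {nm: float(np.sqrt(init_om[j, j]))
                    for j, nm in enumerate(init_re)}
    for i, nm in enumerate(pnames):
        omega[i, i] = FROZEN_VARIANCE if frozen[i] else \
            max(init_sds.get(nm, 0.3), 0.05) ** 2
    error_models = {}
    for v in prob.var_names:
        kind = spec.error_models.get(v, "proportional")
        em = getattr(init, "error_models", {}).get(v)
        if em is not None and em.kind == kind:
            error_models[v] = em
        elif kind == "constant":
            error_models[v] = ErrorModel("constant", a=0.5)
        elif kind == "proportional":
            error_models[v] = ErrorModel("proportional", b=0.3)
        else:
            error_models[v] = ErrorModel("combined", a=0.2, b=0.2)

    c = settings.chains
    n = prob.n
    g = prob.group
    phi = np.tile(mu, (c, n, 1)) + beta * g[None, :, None]
    phi += 0.1 * rng.standard_normal(phi.shape)

    flat = phi.reshape(c * n, p)
    pred = prob.predictions(flat).reshape(c, n, prob.n_var, prob.n_t)
    err_a, err_b = _error_vectors(error_models, prob.var_names)
    ll = np.stack([prob.loglik_obs(pred[i], err_a, err_b) for i in range(c)])

    s1 = phi.mean(axis=0).copy()                       # (N, P)
    s2 = np.einsum("cnp,cnq->pq", phi, phi) / c        # (P, P)
    y_safe = np.where(prob.mask, prob.y, 0.0)
    res2 = np.where(prob.mask, ((y_safe[None] - pred) ** 2).mean(axis=0), 0.0)
    rel2 = np.where(prob.mask,
                    (((y_safe[None] - pred) / np.maximum(pred, 1e-12)) ** 2)
                    .mean(axis=0), 0.0)
    spred = np.where(prob.mask, pred.mean(axis=0), 0.0)

    steps = np.full(p, 0.4)
    joint_step = 0.5
    active_idx = np.array([i for i, nm in enumerate(pnames)
                           if nm in prob.active_params], dtype=int)
    # adaptive per-patient proposal covariance (Haario-style), captures the
    # strong within-patient posterior correlations along model ridges
    ad_mean = phi.mean(axis=0).copy()
    ad_cov = np.tile(np.eye(p) * 0.04, (n, 1, 1))
    ad_step = 1.0
    k_total = settings.k_explore + settings.k_smooth
    trace_rows = []

    def chol_inv(om):
        L = np.linalg.cholesky(om)
        w = np.linalg.inv(om)
        logdet = 2 * np.log(np.diag(L)).sum()
        return w, logdet

    w_om, _ = chol_inv(omega)

    def log_prior(ph):
        eta = ph - (mu + beta * g[None, :, None])
        return -0.5 * np.einsum("cnp,pq,cnq->cn", eta, w_om, eta)

    lp = log_prior(phi)

    for k in range(1, k_total + 1):
        exploring = k <= settings.k_explore
        gamma = 1.0 if exploring else (k - settings.k_explore) ** (-settings.step_exponent)

        mean_i = mu + beta * g[:, None]                # (N, P)
        # kernel 1: independent proposal from the population distribution
        cand = mean_i[None] + rng.multivariate_normal(
            np.zeros(p), omega, size=(c, n), method="cholesky")
        cand_pred = prob.predictions(cand.reshape(c * n, p)).reshape(pred.shape)
        cand_ll = np.stack([prob.loglik_obs(cand_pred[i], err_a, err_b)
                            for i in range(c)])
        accept = np.log(rng.random((c, n))) < cand_ll - ll
        phi = np.where(accept[..., None], cand, phi)
        pred = np.where(accept[..., None, None], cand_pred, pred)
        ll = np.where(accept, cand_ll, ll)
        lp = log_prior(phi)

        # kernel 2: joint random walk scaled by the current Omega (captures
        # posterior correlations the componentwise kernel mixes slowly along)
        for _ in range(settings.mh_steps):
            cand = phi + joint_step * rng.multivariate_normal(
                np.zeros(p), omega, size=(c, n), method="cholesky")
            cand_pred = prob.predictions(
                cand.reshape(c * n, p)).reshape(pred.shape)
            cand_ll = np.stack([prob.loglik_obs(cand_pred[i], err_a, err_b)
                                for i in range(c)])
            cand_lp = log_prior(cand)
            accept = np.log(rng.random((c, n))) < \
                (cand_ll + cand_lp) - (ll + lp)
            phi = np.where(accept[..., None], cand, phi)
            pred = np.where(accept[..., None, None], cand_pred, pred)
            ll = np.where(accept, cand_ll, ll)
            lp = np.where(accept, cand_lp, lp)
            joint_step = float(np.clip(
                joint_step * np.exp(0.4 * (accept.mean() -
                                           settings.target_acceptance)),
                1e-5, 2.0))

        # kernel 3: per-patient adaptive-covariance random walk
        pm = phi.mean(axis=0)
        ad_mean += 0.02 * (pm - ad_mean)
        dev = pm - ad_mean
        ad_cov += 0.02 * (dev[:, :, None] * dev[:, None, :] - ad_cov)
        if k > 30:
            chol_ad = np.linalg.cholesky(
                ad_cov + 1e-4 * np.eye(p)[None])
            for _ in range(settings.mh_steps):
                z = rng.standard_normal((c, n, p))
                cand = phi + ad_step * (2.38 / np.sqrt(p)) * np.einsum(
                    "npq,cnq->cnp", chol_ad, z)
                cand_pred = prob.predictions(
                    cand.reshape(c * n, p)).reshape(pred.shape)
                cand_ll = np.stack([prob.loglik_obs(cand_pred[i], err_a, err_b)
                                    for i in range(c)])
                cand_lp = log_prior(cand)
                accept = np.log(rng.random((c, n))) < \
                    (cand_ll + cand_lp) - (ll + lp)
                phi = np.where(accept[..., None], cand, phi)
                pred = np.where(accept[..., None, None], cand_pred, pred)
                ll = np.where(accept, cand_ll, ll)
                lp = np.where(accept, cand_lp, lp)
                ad_step = float(np.clip(
                    ad_step * np.exp(0.4 * (accept.mean() -
                                            settings.target_acceptance)),
                    1e-5, 10.0))

        # kernel 4: adaptive componentwise random walks (active params only)
        for _ in range(settings.mh_steps):
            order = rng.permutation(active_idx)
            acc_count = np.full(p, settings.target_acceptance)
            for j in order:
                cand = phi.copy()
                cand[..., j] += steps[j] * rng.standard_normal((c, n))
                cand_pred = prob.predictions(
                    cand.reshape(c * n, p)).reshape(pred.shape)
                cand_ll = np.stack([prob.loglik_obs(cand_pred[i], err_a, err_b)
                                    for i in range(c)])
                cand_lp = log_prior(cand)
                accept = np.log(rng.random((c, n))) < \
                    (cand_ll + cand_lp) - (ll + lp)
                phi = np.where(accept[..., None], cand, phi)
                pred = np.where(accept[..., None, None], cand_pred, pred)
                ll = np.where(accept, cand_ll, ll)
                lp = np.where(accept, cand_lp, lp)
                acc_count[j] = accept.mean()
            steps = np.clip(steps * np.exp(0.4 * (acc_count -
                                                  settings.target_acceptance)),
                            1e-5, 2.0)

        # SA update of sufficient statistics
        s1 += gamma * (phi.mean(axis=0) - s1)
        s2 += gamma * (np.einsum("cnp,cnq->pq", phi, phi) / c - s2)
        cur_res2 = np.where(prob.mask,
                            ((y_safe[None] - pred) ** 2).mean(axis=0), 0.0)
        cur_rel2 = np.where(prob.mask,
                            (((y_safe[None] - pred)
                              / np.maximum(pred, 1e-12)) ** 2).mean(axis=0),
                            0.0)
        cur_pred = np.where(prob.mask, pred.mean(axis=0), 0.0)
        res2 += gamma * (cur_res2 - res2)
        rel2 += gamma * (cur_rel2 - rel2)
        spred += gamma * (cur_pred - spred)

        # M-step
        mu, beta_full = _mstep_fixed_effects(s1, g, omega, cov_idx)
        beta = beta_full
        mean_i = mu + beta * g[:, None]
        om_new = (s2 - mean_i.T @ s1 - s1.T @ mean_i
                  + mean_i.T @ mean_i) / n
        om_new = 0.5 * (om_new + om_new.T)
        if settings.annealing and exploring:
            d_floor = 0.95 * np.diag(omega)
            dd = np.maximum(np.diag(om_new), d_floor)
            om_new[np.diag_indices_from(om_new)] = dd
        omega = _restrict_omega(om_new, mask_struct, frozen, events)

        anneal_floor = None
        if settings.annealing and exploring:
            anneal_floor = {v: (0.95 * error_models[v].a,
                                0.95 * error_models[v].b)
                            for v in prob.var_names}
        error_models = _update_error_models(
            {v: error_models[v].kind for v in prob.var_names},
            prob.var_names, res2, rel2, spred, prob.mask, error_models,
            anneal_floor)
        err_a, err_b = _error_vectors(error_models, prob.var_names)

        w_om, _ = chol_inv(omega)
        ll = np.stack([prob.loglik_obs(pred[i], err_a, err_b)
                       for i in range(c)])
        lp = log_prior(phi)

        row = {"iteration": k, "phase": "explore" if exploring else "smooth"}
        row.update({f"theta_{nm}": float(np.exp(mu[i]))
                    for i, nm in enumerate(pnames)})
        row.update({f"beta_{nm}": float(beta[i])
                    for i, nm in enumerate(pnames) if nm in spec.covariates})
        row.update({f"omega_{nm}": float(np.sqrt(omega[i, i]))
                    for i, nm in enumerate(pnames) if not frozen[i]})
        for v in prob.var_names:
            row[f"err_{v}_a"] = error_models[v].a
            row[f"err_{v}_b"] = error_models[v].b
        trace_rows.append(row)

    trace = pd.DataFrame(trace_rows)
    theta_pop = {nm: float(np.exp(mu[i])) for i, nm in enumerate(pnames)}
    beta_d = {nm: float(beta[i]) for i, nm in enumerate(pnames)
              if nm in spec.covariates}
    if not np.all(np.isfinite(mu)):
        raise NonConvergenceError("divergent SAEM trace (non-finite estimates)")
    fit = PopulationFit(theta_pop=theta_pop, beta=beta_d, omega=omega,
                        omega_names=pnames, error_models=error_models,
                        trace=trace, spec=spec, settings=settings,
                        seed=settings.seed, problem=prob, events=events)
    fit._phi_last = phi.mean(axis=0)
    return fit


# ---------------------------------------------------------------------------
# post-fit quantities


def _patient_logpost_factory(fit: PopulationFit):
    prob = fit.problem
    mu = fit.mu_vector()
    beta = fit.beta_vector()
    w = np.linalg.inv(fit.omega)
    err_a, err_b = _error_vectors(fit.error_models, prob.var_names)

    def neg_logpost(phi_vec: np.ndarray, i: int) -> float:
        pred = prob.predictions(phi_vec[None])[0]
        sd = np.maximum(err_a[:, None] + err_b[:, None] * pred, _MIN_ERROR_SD)
        r = (prob.y[i] - pred) / sd
        ll = -0.5 * np.sum((np.log(2 * np.pi * sd**2) + r**2)[prob.mask[i]])
        eta = phi_vec - (mu + beta * prob.group[i])
        return float(-ll + 0.5 * eta @ w @ eta)

    return neg_logpost


def conditional_modes(fit: PopulationFit, warn: bool = True) -> pd.DataFrame:
    """Empirical Bayes estimates: per-patient MAP of the log-parameters.

    Patients with no informative data shrink fully to the population mean.
    Returns a DataFrame of natural-scale parameters indexed by patient id.
    """
    prob = fit.problem
    neg_logpost = _patient_logpost_factory(fit)
    mu = fit.mu_vector()
    beta = fit.beta_vector()
    rows = []
    modes = np.empty((prob.n, len(prob.param_names)))
    for i in range(prob.n):
        x0 = mu + beta * prob.group[i]
        start = fit._phi_last[i] if hasattr(fit, "_phi_last") else x0
        f_prior = neg_logpost(x0, i)
        best = None
        for s in (start, x0):
            res = optimize.minimize(neg_logpost, s, args=(i,),
                                    method="L-BFGS-B",
                                    options={"maxiter": 300})
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun) or best.fun > f_prior + 1e-6:
            modes[i] = x0 if best.fun > f_prior else best.x
        else:
            modes[i] = best.x
        rows.append({"patient_id": prob.patient_ids[i],
                     **{nm: float(np.exp(modes[i, j]))
                        for j, nm in enumerate(prob.param_names)}})
    ebes = pd.DataFrame(rows).set_index("patient_id")
    fit.ebes = ebes
    fit._phi_modes = modes
    return ebes


def _posterior_samples(fit: PopulationFit, n_sweeps: int = 200,
                       seed: int | None = None):
    """Short MH run at the final estimates; returns per-patient samples."""
    prob = fit.problem
    rng = np.random.default_rng(fit.seed + 9001 if seed is None else seed)
    p = len(prob.param_names)
    mu = fit.mu_vector()
    beta = fit.beta_vector()
    mean_i = mu + beta * prob.group[:, None]
    w = np.linalg.inv(fit.omega)
    err_a, err_b = _error_vectors(fit.error_models, prob.var_names)
    phi = fit._phi_last.copy() if hasattr(fit, "_phi_last") else mean_i.copy()
    pred = prob.predictions(phi)
    ll = prob.loglik_obs(pred, err_a, err_b)

    def lp_of(ph):
        eta = ph - mean_i
        return -0.5 * np.einsum("np,pq,nq->n", eta, w, eta)

    lp = lp_of(phi)
    steps = np.full(p, 0.3)
    active_idx = [i for i, nm in enumerate(prob.param_names)
                  if nm in prob.active_params]
    keep = []
    for k in range(n_sweeps):
        cand = mean_i + rng.multivariate_normal(np.zeros(p), fit.omega,
                                                size=prob.n, method="cholesky")
        cll = prob.loglik_obs(prob.predictions(cand), err_a, err_b)
        acc = np.log(rng.random(prob.n)) < cll - ll
        phi = np.where(acc[:, None], cand, phi)
        ll = np.where(acc, cll, ll)
        lp = lp_of(phi)
        for j in active_idx:
            cand = phi.copy()
            cand[:, j] += steps[j] * rng.standard_normal(prob.n)
            cll = prob.loglik_obs(prob.predictions(cand), err_a, err_b)
            clp = lp_of(cand)
            acc = np.log(rng.random(prob.n)) < (cll + clp) - (ll + lp)
            phi = np.where(acc[:, None], cand, phi)
            ll = np.where(acc, cll, ll)
            lp = np.where(acc, clp, lp)
            steps[j] = np.clip(steps[j] * np.exp(0.3 * (acc.mean() - 0.3)),
                               1e-3, 2.0)
        if k >= n_sweeps // 4:
            keep.append(phi.copy())
    return np.array(keep)  # (S, N, P)


def _mvt_logpdf(x, mean, chol, df):
    from scipy.linalg import solve_triangular
    p = mean.shape[-1]
    d = x - mean
    sol = solve_triangular(chol, d.T, lower=True).T
    q = np.sum(sol**2, axis=-1)
    logdet = np.sum(np.log(np.diag(chol)))
    return (gammaln((df + p) / 2) - gammaln(df / 2)
            - 0.5 * p * np.log(df * np.pi) - logdet
            - 0.5 * (df + p) * np.log1p(q / df))


def estimate_loglikelihood(fit: PopulationFit, n_importance: int = 1000,
                           seed: int | None = None):
    """Importance-sampled marginal -2 log-likelihood and its Monte-Carlo SE.

    Per patient, draws from a multivariate t (df 5) centred at the posterior
    mean with 1.3x the posterior covariance estimated from a short MH run.
    """
    prob = fit.problem
    rng = np.random.default_rng((fit.seed + 7177) if seed is None else seed)
    samples = _posterior_samples(fit, n_sweeps=150, seed=rng.integers(2**31))
    centers = samples.mean(axis=0)                     # (N, P)
    p = len(prob.param_names)
    mu = fit.mu_vector()
    beta = fit.beta_vector()
    mean_i = mu + beta * prob.group[:, None]

    # integrate only over dimensions the likelihood can see (plus any
    # random effects coupled to them through Omega); the rest factor out of
    # the marginal integral exactly
    active = {i for i, nm in enumerate(prob.param_names)
              if nm in prob.active_params}
    coupled = True
    while coupled:
        extra = {j for j in range(p) if j not in active
                 and np.any(np.abs(fit.omega[j, list(active)]) > 0)}
        coupled = bool(extra)
        active |= extra
    idx = np.array(sorted(active), dtype=int)
    d = idx.size

    om_sub = fit.omega[np.ix_(idx, idx)]
    w = np.linalg.inv(om_sub)
    sign, logdet_om = np.linalg.slogdet(om_sub)
    err_a, err_b = _error_vectors(fit.error_models, prob.var_names)

    covs = np.empty((prob.n, d, d))
    for i in range(prob.n):
        c = np.atleast_2d(np.cov(samples[:, i, idx].T))
        covs[i] = 1.3 * c + 1e-8 * np.eye(d)
    df = 5.0
    m = n_importance
    chols = np.linalg.cholesky(covs)
    z = rng.standard_normal((m, prob.n, d))
    u = rng.chisquare(df, size=(m, prob.n)) / df
    draws_sub = centers[:, idx][None] + np.einsum(
        "npq,mnq->mnp", chols, z) / np.sqrt(u)[..., None]

    logq = np.empty((m, prob.n))
    for i in range(prob.n):
        logq[:, i] = _mvt_logpdf(draws_sub[:, i, :], centers[i, idx],
                                 chols[i], df)
    eta = draws_sub - mean_i[:, idx][None]
    logprior = -0.5 * (np.einsum("mnp,pq,mnq->mn", eta, w, eta)
                       + logdet_om + d * np.log(2 * np.pi))
    draws = np.broadcast_to(mean_i, (m, prob.n, p)).copy()
    draws[:, :, idx] = draws_sub
    flat = draws.reshape(m * prob.n, p)
    pred = prob.predictions(flat).reshape(m, prob.n, prob.n_var, prob.n_t)
    logl = np.stack([prob.loglik_obs(pred[j], err_a, err_b) for j in range(m)])

    logw = logl + logprior - logq                      # (M, N)
    li = logsumexp(logw, axis=0) - np.log(m)
    # delta-method Monte-Carlo SE of each patient's log-likelihood
    wmax = logw.max(axis=0)
    wn = np.exp(logw - wmax)
    rel_var = wn.var(axis=0, ddof=1) / np.maximum(wn.mean(axis=0) ** 2, 1e-300)
    se_li = np.sqrt(rel_var / m)
    ess = (wn.sum(axis=0) ** 2) / np.maximum((wn**2).sum(axis=0), 1e-300)
    if np.any(ess < 0.05 * m):
        fit.events.append("low_importance_ess")
    minus2ll = float(-2.0 * li.sum())
    mc_se = float(2.0 * np.sqrt(np.sum(se_li**2)))
    fit.minus2ll = minus2ll
    fit.mc_se = mc_se
    return minus2ll, mc_se


def estimate_standard_errors(fit: PopulationFit, method: str = "louis",
                             n_sweeps: int = 300) -> dict:
    """Standard errors of the fixed effects (log scale) and covariate
    coefficients.

    ``louis``: Fisher information via Louis' identity over MH samples drawn
    at the final estimates.  ``ll_numeric``: numeric Hessian of the
    importance-sampled log-likelihood (common random numbers).
    """
    prob = fit.problem
    pnames = prob.param_names
    cov_idx = [i for i, nm in enumerate(pnames) if nm in fit.spec.covariates]
    dim = len(pnames) + len(cov_idx)

    if method == "louis":
        samples = _posterior_samples(fit, n_sweeps=n_sweeps)
        w = np.linalg.inv(fit.omega)
        mu = fit.mu_vector()
        beta = fit.beta_vector()
        mean_i = mu + beta * prob.group[:, None]
        eta = samples - mean_i[None]                   # (S, N, P)
        score_mu = np.einsum("pq,snq->snp", w, eta)
        blocks = [score_mu]
        if cov_idx:
            score_beta = score_mu[:, :, cov_idx] * prob.group[None, :, None]
            blocks.append(score_beta)
        scores = np.concatenate(blocks, axis=2)        # (S, N, dim)
        fim = np.zeros((dim, dim))
        pp = len(pnames)
        for i in range(prob.n):
            d = np.zeros((pp, dim))
            d[:, :pp] = np.eye(pp)
            for j, ci in enumerate(cov_idx):
                d[ci, pp + j] = prob.group[i]
            h_i = d.T @ w @ d
            v_i = np.cov(scores[:, i, :].T, ddof=1)
            fim += h_i - v_i
    elif method == "ll_numeric":
        fim = _numeric_fim(fit, cov_idx)
    else:
        raise ValidationError(f"unknown SE method {method!r}")

    try:
        cov = np.linalg.inv(fim)
        flagged = []
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(fim)
        flagged = ["fim_singular"]
        fit.events.append("fim_pseudo_inverse")
    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        flagged.append("negative_variance")
        diag = np.abs(diag)
    se = np.sqrt(diag)
    pp = len(pnames)
    ses = {"log_theta_pop": {nm: float(se[i]) for i, nm in enumerate(pnames)},
           "beta": {pnames[ci]: float(se[pp + j])
                    for j, ci in enumerate(cov_idx)},
           "flags": flagged, "method": method}
    fit.ses = ses
    return ses


def _numeric_fim(fit: PopulationFit, cov_idx, h: float = 0.02,
                 n_importance: int = 300) -> np.ndarray:
    """Central-difference Hessian of -loglik in (mu, beta_C), CRN across
    evaluations."""
    pnames = fit.problem.param_names
    pp = len(pnames)
    dim = pp + len(cov_idx)
    base_mu = fit.mu_vector()
    base_beta = fit.beta_vector()
    seed = int(fit.seed + 31337)

    def nll(x):
        mu = x[:pp]
        beta = base_beta.copy()
        for j, ci in enumerate(cov_idx):
            beta[ci] = x[pp + j]
        tmp = replace_fit_means(fit, mu, beta)
        m2, _ = estimate_loglikelihood(tmp, n_importance=n_importance,
                                       seed=seed)
        return 0.5 * m2

    x0 = np.concatenate([base_mu, base_beta[cov_idx]])
    f0 = nll(x0)
    hess = np.zeros((dim, dim))
    fp = np.zeros(dim)
    fm = np.zeros(dim)
    for i in range(dim):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        fp[i], fm[i] = nll(xp), nll(xm)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(dim):
        for j in range(i + 1, dim):
            xpp = x0.copy()
            xpp[[i, j]] += h
            fpp = nll(xpp)
            hess[i, j] = hess[j, i] = \
                (fpp - fp[i] - fp[j] + f0) / h**2
    return hess


def replace_fit_means(fit: PopulationFit, mu: np.ndarray,
                      beta: np.ndarray) -> PopulationFit:
    """Shallow copy of a fit with substituted fixed effects (internal)."""
    pnames = fit.problem.param_names
    new = replace(
        fit,
        theta_pop={nm: float(np.exp(mu[i])) for i, nm in enumerate(pnames)},
        beta={nm: float(beta[i]) for i, nm in enumerate(pnames)
              if nm in fit.spec.covariates},
        ses=dict(fit.ses), events=list(fit.events))
    if hasattr(fit, "_phi_last"):
        new._phi_last = fit._phi_last
    return new


def wald_test_covariate(fit: PopulationFit, param: str):
    """Wald test of the group coefficient on ``param`` against zero."""
    from .stats import wald_z
    if param not in fit.spec.covariates:
        raise ValidationError(f"{param} carries no covariate in this model")
    if not fit.ses or param not in fit.ses.get("beta", {}):
        raise ValidationError("standard errors not available; run "
                              "estimate_standard_errors first")
    return wald_z(fit.beta[param], fit.ses["beta"][param])
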