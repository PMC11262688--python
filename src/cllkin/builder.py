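"""Automatic statistical-model building for the population model.

Starting from a set of initial configurations, the builder iterates three
move classes — per-variable error-model swaps, group-covariate addition or
removal per parameter, and correlation-block proposals from empirical-Bayes
correlations — accepting a move only when the corrected Bayesian information
criterion (BICc) improves.  The final model is the intersection of the
features selected from every initial configuration, and a multi-start pass
over the fixed effects checks practical identifiability.

BICc uses the hybrid mixed-model penalty: subject-level parameters (fixed
effects, covariate coefficients, free random-effect covariance entries) are
penalised with ``log(n_subjects)``, observation-level (error) parameters
with ``log(n_obs)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import PARAM_NAMES
from .exceptions import NonConvergenceError, ValidationError
from .nlme import (NLMEModelSpec, PopulationFit, SAEMSettings, SAEMProblem,
                   conditional_modes, estimate_loglikelihood, saem_fit)

#: Wald p-value threshold for the cheap EBE-regression covariate screen.
COVARIATE_SCREEN_ALPHA = 0.05
#: |r| threshold on EBE correlations for proposing a correlation block.
CORRELATION_SCREEN_R = 0.5


def bicc(minus2ll: float, n_subjects: int, n_obs: int,
         k_subject_level: int, k_obs_level: int) -> float:
    """Corrected BIC with the mixed subject/observation penalty."""
    if n_subjects < 1 or n_obs < 1:
        raise ValidationError("counts must be positive")
    if k_subject_level < 0 or k_obs_level < 0:
        raise ValidationError("parameter counts must be nonnegative")
    return (minus2ll + k_subject_level * np.log(n_subjects)
            + k_obs_level * np.log(n_obs))


def fit_bicc(fit: PopulationFit, n_importance: int = 500,
             seed: int = 0) -> float:
    """BICc of a converged fit (importance-sampled likelihood)."""
    if not np.isfinite(fit.minus2ll):
        estimate_loglikelihood(fit, n_importance=n_importance, seed=seed)
    return bicc(fit.minus2ll, fit.problem.n, fit.problem.n_obs,
                fit.k_subject_level(), fit.k_obs_level())


@dataclass
class BuildConfig:
    """Configuration of the automatic model builder."""

    initial_specs: list                       # list of NLMEModelSpec
    candidate_covariates: tuple = ("f_in", "F_out", "mu_B", "kappa",
                                   "mu_4", "mu_8", "mu_NK", "mu_reg")
    candidate_blocks: tuple = (("mu_4", "mu_8", "mu_NK", "mu_reg"),
                               ("f_in", "F_out"))
    max_iterations: int = 4
    n_importance: int = 400
    seed: int = 0

    def __post_init__(self):
        if not self.initial_specs:
            raise ValidationError("need at least one initial configuration")


def default_initial_specs(variables: Sequence[str],
                          random_effects: Sequence[str] = PARAM_NAMES) -> list:
    """Five initial configurations spanning error-model, random-effect,
    correlation and covariate choices (constant vs proportional errors, full
    vs partial random-effect sets, with and without the group covariate)."""
    re_full = tuple(random_effects)
    re_partial = tuple(n for n in random_effects
                       if not n.startswith("lam_") and not n.startswith("sig_"))
    mk = lambda kind: {v: kind for v in variables}
    return [
        NLMEModelSpec(re_full, (), (), mk("proportional")),
        NLMEModelSpec(re_full, (), (), mk("constant")),
        NLMEModelSpec(re_full, ("f_in", "F_out", "mu_4"),
                      (("mu_4", "mu_8", "mu_NK", "mu_reg"),),
                      mk("proportional")),
        NLMEModelSpec(re_partial, (), (), mk("proportional")),
        NLMEModelSpec(re_partial, ("F_out",), (), mk("constant")),
    ]


def select_error_model(problem, spec: NLMEModelSpec, settings: SAEMSettings,
                       init, groups=None,
                       n_importance: int = 400, seed: int = 0):
    """Choose constant vs proportional error per variable by BICc.

    Each variable is assessed with the other variables held at the current
    choice; returns (per-variable dict, report rows)."""
    current = dict(spec.error_models)
    rows = []
    var_names = list(current)
    for v in sorted(var_names):
        scores = {}
        for kind in ("constant", "proportional"):
            cand = dict(current)
            cand[v] = kind
            sp = replace_spec(spec, error_models=cand)
            try:
                fit = saem_fit(problem, sp, settings, init, groups=groups)
                scores[kind] = fit_bicc(fit, n_importance, seed)
            except NonConvergenceError:
                scores[kind] = np.inf
        if not np.isfinite(min(scores.values())):
            raise NonConvergenceError(f"both error models failed for {v}")
        best = min(sorted(scores), key=lambda k: scores[k])
        rows.append({"variable": v, "constant": scores["constant"],
                     "proportional": scores["proportional"], "chosen": best})
        current[v] = best
    return current, rows


def replace_spec(spec: NLMEModelSpec, **kw) -> NLMEModelSpec:
    d = {"random_effects": spec.random_effects,
         "covariates": spec.covariates,
         "correlation_blocks": spec.correlation_blocks,
         "error_models": spec.error_models}
    d.update(kw)
    return NLMEModelSpec(**d)


def _covariate_screen(fit: PopulationFit) -> dict:
    """Wald p-value of group on each parameter's EBE log-values."""
    from .stats import wald_z
    ebes = fit.ebes if fit.ebes is not None else conditional_modes(fit)
    g = fit.problem.group
    out = {}
    for nm in fit.problem.param_names:
        x = np.log(ebes[nm].to_numpy())
        n1, n0 = int(g.sum()), int(len(g) - g.sum())
        if n1 < 2 or n0 < 2:
            out[nm] = 1.0
            continue
        d = x[g == 1].mean() - x[g == 0].mean()
        s2 = (x[g == 1].var(ddof=1) / n1 + x[g == 0].var(ddof=1) / n0)
        if s2 <= 0:
            out[nm] = 1.0
            continue
        out[nm] = wald_z(d, np.sqrt(s2)).p_value
    return out


def _block_candidates(fit: PopulationFit, candidate_blocks) -> list:
    """Candidate correlation blocks whose EBE correlations all exceed the
    screening threshold."""
    ebes = fit.ebes if fit.ebes is not None else conditional_modes(fit)
    out = []
    for blk in candidate_blocks:
        r_ok = True
        for a, b in itertools.combinations(blk, 2):
            r = np.corrcoef(np.log(ebes[a]), np.log(ebes[b]))[0, 1]
            if not np.isfinite(r) or abs(r) <= CORRELATION_SCREEN_R:
                r_ok = False
                break
        if r_ok:
            out.append(tuple(blk))
    return out


def build_model(problem, config: BuildConfig, settings: SAEMSettings, init,
                groups=None):
    """Run the iterative builder from every initial configuration.

    Returns ``(final_spec, report DataFrame)``; the final model keeps the
    features common to all per-configuration selections (consensus by
    intersection).  Moves are logged with their BICc change; a move whose
    inner fit fails to converge is rejected and logged.
    """
    per_config_specs = []
    report = []

    for ci, spec0 in enumerate(config.initial_specs):
        spec = spec0
        fit = saem_fit(problem, spec, settings, init, groups=groups)
        score = fit_bicc(fit, config.n_importance, config.seed)
        report.append({"config": ci, "iteration": 0, "move": "initial",
                       "bicc": score, "delta": 0.0, "accepted": True})

        for it in range(1, config.max_iterations + 1):
            improved = False

            # (1) error model selection: try swapping each variable's kind
            for v in sorted(spec.error_models):
                cur_kind = spec.error_models[v]
                alt = "constant" if cur_kind == "proportional" else "proportional"
                cand_err = dict(spec.error_models)
                cand_err[v] = alt
                cand_spec = replace_spec(spec, error_models=cand_err)
                try:
                    cand_fit = saem_fit(problem, cand_spec, settings, init,
                                        groups=groups)
                    cand_score = fit_bicc(cand_fit, config.n_importance,
                                          config.seed)
                except NonConvergenceError:
                    report.append({"config": ci, "iteration": it,
                                   "move": f"error:{v}->{alt}",
                                   "bicc": np.nan, "delta": np.nan,
                                   "accepted": False})
                    continue
                accepted = cand_score < score
                report.append({"config": ci, "iteration": it,
                               "move": f"error:{v}->{alt}",
                               "bicc": cand_score, "delta": cand_score - score,
                               "accepted": accepted})
                if accepted:
                    spec, fit, score = cand_spec, cand_fit, cand_score
                    improved = True

            # (2) covariate screening on EBEs, then BICc-checked refit
            pvals = _covariate_screen(fit)
            for nm in sorted(config.candidate_covariates):
                has = nm in spec.covariates
                want = pvals.get(nm, 1.0) < COVARIATE_SCREEN_ALPHA
                if has == want:
                    continue
                new_cov = tuple(sorted(set(spec.covariates) ^ {nm}))
                cand_spec = replace_spec(spec, covariates=new_cov)
                try:
                    cand_fit = saem_fit(problem, cand_spec, settings, init,
                                        groups=groups)
                    cand_score = fit_bicc(cand_fit, config.n_importance,
                                          config.seed)
                except NonConvergenceError:
                    report.append({"config": ci, "iteration": it,
                                   "move": f"cov{'-' if has else '+'}{nm}",
                                   "bicc": np.nan, "delta": np.nan,
                                   "accepted": False})
                    continue
                accepted = cand_score < score
                report.append({"config": ci, "iteration": it,
                               "move": f"cov{'-' if has else '+'}{nm}",
                               "bicc": cand_score, "delta": cand_score - score,
                               "accepted": accepted})
                if accepted:
                    spec, fit, score = cand_spec, cand_fit, cand_score
                    improved = True

            # (3) correlation blocks from EBE correlations
            for blk in _block_candidates(fit, config.candidate_blocks):
                if blk in spec.correlation_blocks:
                    continue
                if any(set(blk) & set(b) for b in spec.correlation_blocks):
                    continue
                if set(blk) - set(spec.random_effects):
                    continue
                cand_spec = replace_spec(
                    spec, correlation_blocks=spec.correlation_blocks + (blk,))
                try:
                    cand_fit = saem_fit(problem, cand_spec, settings, init,
                                        groups=groups)
                    cand_score = fit_bicc(cand_fit, config.n_importance,
                                          config.seed)
                except NonConvergenceError:
                    report.append({"config": ci, "iteration": it,
                                   "move": f"corr+{'/'.join(blk)}",
                                   "bicc": np.nan, "delta": np.nan,
                                   "accepted": False})
                    continue
                accepted = cand_score < score
                report.append({"config": ci, "iteration": it,
                               "move": f"corr+{'/'.join(blk)}",
                               "bicc": cand_score, "delta": cand_score - score,
                               "accepted": accepted})
                if accepted:
                    spec, fit, score = cand_spec, cand_fit, cand_score
                    improved = True

            if not improved:
                break
        per_config_specs.append(spec)

    final = consensus_spec(per_config_specs)
    return final, pd.DataFrame(report)


def consensus_spec(specs: Sequence[NLMEModelSpec]) -> NLMEModelSpec:
    """Intersection of the features selected across configurations."""
    covs = set(specs[0].covariates)
    blocks = set(specs[0].correlation_blocks)
    re = set(specs[0].random_effects)
    for s in specs[1:]:
        covs &= set(s.covariates)
        blocks &= set(s.correlation_blocks)
        re |= set(s.random_effects)
    err = {}
    for v in specs[0].error_models:
        kinds = {s.error_models[v] for s in specs}
        err[v] = kinds.pop() if len(kinds) == 1 else "proportional"
    re_t = tuple(n for n in PARAM_NAMES if n in re) or specs[0].random_effects
    blocks = tuple(sorted(b for b in blocks if not (set(b) - set(re_t))))
    return NLMEModelSpec(random_effects=re_t,
                         covariates=tuple(sorted(covs)),
                         correlation_blocks=blocks,
                         error_models=err)


def multi_start(problem, spec: NLMEModelSpec, init, n_starts: int = 5,
                perturbation_factor: float = 3.0,
                settings: SAEMSettings | None = None, groups=None,
                spread_threshold: float = 0.10) -> pd.DataFrame:
    """Robustness of the fixed effects to perturbed initial values.

    Runs SAEM from ``n_starts`` log-uniformly perturbed initial fixed-effect
    vectors and reports the relative spread (max/min - 1) of each final
    estimate with a practical-identifiability verdict."""
    if n_starts < 2:
        raise ValidationError("n_starts must be >= 2")
    settings = settings or SAEMSettings()
    rng = np.random.default_rng(settings.seed + 1234)
    results = []
    failures = 0
    for s in range(n_starts):
        pert = dict(init.theta_pop)
        if s > 0:
            for nm in pert:
                pert[nm] = float(pert[nm] * np.exp(
                    rng.uniform(-np.log(perturbation_factor),
                                np.log(perturbation_factor))))
        init_s = _InitLike(pert, dict(getattr(init, "beta", {})),
                           dict(getattr(init, "error_models", {})))
        try:
            fit = saem_fit(problem, spec,
                           replace(settings, seed=settings.seed + s),
                           init_s, groups=groups)
            results.append(fit.theta_pop)
        except NonConvergenceError:
            failures += 1
    if not results:
        raise NonConvergenceError("all multi-start runs failed")
    rows = []
    for nm in results[0]:
        vals = np.array([r[nm] for r in results])
        spread = float(vals.max() / vals.min() - 1.0)
        rows.append({"parameter": nm, "spread": spread,
                     "identifiable": spread < spread_threshold,
                     "n_converged": len(results)})
    return pd.DataFrame(rows)


class _InitLike:
    def __init__(self, theta_pop, beta, error_models):
        self.theta_pop = theta_pop
        self.beta = beta
        self.error_models = error_models
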