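"""End-to-end pipeline driver: classify -> summarise -> fit group means ->
fit population model (-> optional automatic model building), with a run
manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import classify_cohort, summarize_group
from .cohort import emulate_study_scenario, generate_cohort
from .exceptions import CllkinError, PipelineError
from .io import load_config, read_cohort, write_cohort
from .meanfit import fit_group_means, mean_dataset_from_observations, profile_likelihood_ci
from .nlme import (NLMEModelSpec, SAEMSettings, estimate_loglikelihood,
                   estimate_standard_errors, make_ode_problem, saem_fit,
                   wald_test_covariate)


def _series_to_frame(cohort):
    rows = []
    for p in cohort:
        for var, (days, vals) in p.series.items():
            for d, v in zip(days, vals):
                rows.append((p.patient_id, d, var, v,
                             "GperL" if var == "ALC" else "fold_change"))
    return pd.DataFrame(rows, columns=["patient_id", "time_days", "variable",
                                       "value", "unit"])


def run_pipeline(config_path, outdir=None) -> dict:
    """Run the configured stages; writes CSV artifacts plus a manifest.

    Returns a dict of output paths.  Any stage failure raises
    :class:`PipelineError` naming the stage; partial outputs are kept next to
    a FAILED marker file.
    """
    cfg = load_config(config_path)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    seed = int(cfg["seed"])
    artifacts = {}
    stage = "setup"
    try:
        stage = "load"
        if cfg["scenario"] == "packaged":
            pop, design = emulate_study_scenario(
                n_thl=int(cfg["n_thl"]), n_phl=int(cfg["n_phl"]), seed=seed)
            obs, cov, truth = generate_cohort(pop, design)
            cov_out = cov.copy()
            write_cohort(obs, cov_out, out / "observations.csv",
                         out / "covariates.csv")
            truth.to_csv(out / "truth.csv", index=False)
            artifacts["truth"] = str(out / "truth.csv")
            cohort = read_cohort(out / "observations.csv",
                                 out / "covariates.csv")
            init = pop
        else:
            cohort = read_cohort(cfg["observations"], cfg["covariates"])
            obs = _series_to_frame(cohort)
            pop, _ = emulate_study_scenario(seed=seed)
            init = pop

        groups = {}
        if "classify" in cfg["stages"]:
            stage = "classify"
            cls = classify_cohort(cohort)
            cls.to_csv(out / "classification.csv", index=False)
            artifacts["classification"] = str(out / "classification.csv")
            groups = {r.patient_id: r.group_assigned for r in cls.itertuples()
                      if r.group_assigned in ("tHL", "pHL")}
            for p in cohort:
                p.group = groups.get(p.patient_id)

        if "summarize" in cfg["stages"]:
            stage = "summarize"
            tabs = []
            for var in ("ALC", "B_bl", "T4", "T8", "TNK", "Treg"):
                try:
                    t = summarize_group(cohort, var, "median", percent=True)
                except CllkinError:
                    continue
                t.insert(0, "variable", var)
                tabs.append(t)
            pd.concat(tabs).to_csv(out / "group_summaries.csv", index=False)
            artifacts["group_summaries"] = str(out / "group_summaries.csv")

        if "fit_means" in cfg["stages"]:
            stage = "fit_means"
            datasets = mean_dataset_from_observations(obs, groups)
            if not datasets:
                raise PipelineError("fit_means",
                                    "no classified patients available")
            rows = []
            for grp, ds in sorted(datasets.items()):
                fr = fit_group_means(ds, init.theta_pop, seed=seed,
                                     n_restarts=2)
                lo, hi, _ = profile_likelihood_ci(fr, ds, "F_out",
                                                  grid_spec=(10.0, 13))
                rows.append({"group": grp, **fr.estimates,
                             "minus2ll": fr.minus2ll, "aicc": fr.aicc,
                             "F_out_ci_lo": lo, "F_out_ci_hi": hi})
            pd.DataFrame(rows).to_csv(out / "mean_fits.csv", index=False)
            artifacts["mean_fits"] = str(out / "mean_fits.csv")

        if "fit_population" in cfg["stages"]:
            stage = "fit_population"
            spec = NLMEModelSpec(
                covariates=("f_in", "F_out", "mu_4"),
                correlation_blocks=(("mu_4", "mu_8", "mu_NK", "mu_reg"),
                                    ("f_in", "F_out")),
                error_models={v: "proportional"
                              for v in ("B_LN", "B_bl", "T4", "T8",
                                        "TNK", "Treg")})
            settings = SAEMSettings(k_explore=int(cfg["saem"]["k_explore"]),
                                    k_smooth=int(cfg["saem"]["k_smooth"]),
                                    seed=seed)
            problem = make_ode_problem(obs, groups)
            fit = saem_fit(problem, spec, settings, init)
            estimate_loglikelihood(fit, n_importance=500, seed=seed + 1)
            estimate_standard_errors(fit)
            est = pd.DataFrame([
                {"parameter": n, "theta_pop": fit.theta_pop[n],
                 "beta_group": fit.beta.get(n, np.nan),
                 "se_log_theta": fit.ses["log_theta_pop"][n],
                 "se_beta": fit.ses["beta"].get(n, np.nan)}
                for n in fit.param_names])
            est.to_csv(out / "population_estimates.csv", index=False)
            fit.trace.to_csv(out / "saem_trace.csv", index=False)
            wrows = []
            for nm in spec.covariates:
                r = wald_test_covariate(fit, nm)
                wrows.append({"parameter": nm, "beta": fit.beta[nm],
                              "se": fit.ses["beta"][nm],
                              "z": r.statistic, "p_value": r.p_value})
            pd.DataFrame(wrows).to_csv(out / "wald_tests.csv", index=False)
            artifacts["population_estimates"] = str(out / "population_estimates.csv")
            artifacts["wald_tests"] = str(out / "wald_tests.csv")
            artifacts["saem_trace"] = str(out / "saem_trace.csv")

        stage = "manifest"
        cfg_text = Path(config_path).read_text()
        manifest = {
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "seed": seed,
            "version": __version__,
            "stages": cfg["stages"],
            "wall_clock_s": round(time.time() - t_start, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        artifacts["manifest"] = str(out / "manifest.json")
        return artifacts
    except CllkinError as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
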