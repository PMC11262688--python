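"""Cohort file formats, configuration and validation.

Observations are long (tidy) CSV — one row per (patient, day, variable) —
because lymph-node imaging and blood sampling follow different visit
schedules.  All times are stored in days; monthly visit labels are derived
annotations, never keys.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import PatientSeries
from .exceptions import SchemaError, ValidationError

OBS_COLUMNS = ("patient_id", "time_days", "variable", "value", "unit")
COV_COLUMNS = ("patient_id", "b2m_mg_per_L", "hb_g_per_L", "ldh_uln_ratio",
               "months_since_last_therapy")
KNOWN_VARIABLES = ("ALC", "B_bl", "T4", "T8", "TNK", "Treg", "B_LN")
KNOWN_UNITS = ("GperL", "fold_change", "ml")


def write_cohort(observations: pd.DataFrame, covariates: pd.DataFrame,
                 obs_path, cov_path) -> None:
    observations.to_csv(obs_path, index=False)
    covariates.to_csv(cov_path, index=False)


def _schema_fail(path, row, message):
    where = f"{path}" + (f", line {row + 2}" if row is not None else "")
    raise SchemaError(f"{where}: {message}")


def read_cohort(observations_path, covariates_path) -> list[PatientSeries]:
    """Read and validate a cohort; returns a list of PatientSeries.

    Schema violations raise with file and line number; duplicate
    (patient, time, variable) keys are rejected listing the duplicates.
    """
    obs_path, cov_path = Path(observations_path), Path(covariates_path)
    try:
        obs = pd.read_csv(obs_path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{obs_path}: empty observations file")
    cov = pd.read_csv(cov_path)

    missing = set(OBS_COLUMNS) - set(obs.columns)
    if missing:
        _schema_fail(obs_path, None, f"missing columns {sorted(missing)}")
    if obs.empty:
        raise SchemaError(f"{obs_path}: no observation rows")
    missing = set(COV_COLUMNS) - set(cov.columns)
    if missing:
        _schema_fail(cov_path, None, f"missing columns {sorted(missing)}")

    for i, row in obs.iterrows():
        if row.variable not in KNOWN_VARIABLES:
            _schema_fail(obs_path, i, f"unknown variable {row.variable!r}")
        if row.unit not in KNOWN_UNITS:
            _schema_fail(obs_path, i, f"unknown unit {row.unit!r}")
        if not np.isfinite(row.time_days) or row.time_days < 0:
            _schema_fail(obs_path, i, f"bad time_days {row.time_days!r}")
        if not np.isfinite(row.value) or row.value < 0:
            _schema_fail(obs_path, i, f"bad value {row.value!r}")

    dup = obs.duplicated(subset=["patient_id", "time_days", "variable"])
    if dup.any():
        keys = obs.loc[dup, ["patient_id", "time_days", "variable"]]
        raise SchemaError(
            f"{obs_path}: duplicate (patient, time, variable) rows: "
            f"{keys.to_records(index=False).tolist()} "
            f"(first at line {int(keys.index[0]) + 2})")

    unknown_pat = set(obs.patient_id) - set(cov.patient_id)
    if unknown_pat:
        _schema_fail(obs_path, None,
                     f"patients missing from covariates: {sorted(unknown_pat)}")

    cov = cov.set_index("patient_id")
    out = []
    for pid, sub in obs.groupby("patient_id", sort=True):
        series = {}
        for var, vsub in sub.groupby("variable"):
            vsub = vsub.sort_values("time_days")
            series[var] = (vsub.time_days.to_numpy(dtype=float),
                           vsub.value.to_numpy(dtype=float))
        c = cov.loc[pid]
        covariates = {k: (float(c[k]) if np.isfinite(c[k]) else None)
                      for k in COV_COLUMNS if k != "patient_id"}
        group = None
        if "group" in cov.columns and isinstance(c.get("group"), str) \
                and c.get("group") in ("tHL", "pHL"):
            group = c["group"]
        out.append(PatientSeries(patient_id=str(pid), series=series,
                                 covariates=covariates, group=group))
    return out


DEFAULT_CONFIG = {
    "seed": 0,
    "scenario": "packaged",          # packaged | files
    "observations": None,
    "covariates": None,
    "n_thl": 28,
    "n_phl": 13,
    "stages": ["classify", "summarize", "fit_means", "fit_population"],
    "saem": {"k_explore": 300, "k_smooth": 200},
    "outdir": "cllkin_out",
}

_ALLOWED_KEYS = set(DEFAULT_CONFIG)


def load_config(path) -> dict:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(raw)
    if cfg["scenario"] not in ("packaged", "files"):
        raise ValidationError(f"unknown scenario {cfg['scenario']!r}")
    if cfg["scenario"] == "files" and not (cfg["observations"]
                                           and cfg["covariates"]):
        raise ValidationError("scenario 'files' needs observations/covariates")
    bad = set(cfg["stages"]) - {"classify", "summarize", "fit_means",
                                "fit_population", "build_model"}
    if bad:
        raise ValidationError(f"unknown stage(s): {sorted(bad)}")
    return cfg


def parameters_from_config(path) -> dict:
    """Read a key = value parameter file ('#' comments allowed)."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}, line {ln}: expected key = value")
        k, v = (s.strip() for s in line.split("=", 1))
        try:
            out[k] = float(v)
        except ValueError:
            raise ValidationError(f"{path}, line {ln}: non-numeric value {v!r}")
    return out
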