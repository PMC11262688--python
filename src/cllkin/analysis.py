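"""Patient-level longitudinal analysis: lymphocytosis classification,
percent-change summaries, the BALL prognostic score and group comparisons.

Patients are split by their absolute lymphocyte count (ALC) response to
treatment: prolonged hyperlymphocytosis (pHL) means the ALC at month 3
strictly exceeds its pre-treatment (month 0) value; transient (tHL) means it
does not.  Visits are matched by nearest day within a tolerance because real
visit dates jitter around their monthly labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_MONTH
from .exceptions import MissingCovariateError, SchemaError, ValidationError
from . import stats as _stats

logger = logging.getLogger(__name__)

#: Default nearest-visit matching window, days.
DEFAULT_TOLERANCE_DAYS = 14.0

BALL_BANDS = {"low": (0, 1), "intermediate": (2, 3), "high": (4, 4)}


@dataclass
class PatientSeries:
    """One patient's observed longitudinal series plus baseline covariates.

    ``series`` maps variable name -> (days, values) arrays; blood counts are
    in G/L, the lymph-node burden is a dimensionless fold-change.
    """

    patient_id: str
    series: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    group: str | None = None

    def __post_init__(self):
        clean = {}
        for var, (days, values) in self.series.items():
            days = np.asarray(days, dtype=float)
            values = np.asarray(values, dtype=float)
            if days.ndim != 1 or days.shape != values.shape:
                raise ValidationError(f"{self.patient_id}/{var}: malformed series")
            if np.any(days < 0):
                raise ValidationError(f"{self.patient_id}/{var}: negative day")
            if days.size > 1 and not np.all(np.diff(days) > 0):
                raise ValidationError(
                    f"{self.patient_id}/{var}: days must be strictly increasing")
            if np.any(values < 0):
                raise ValidationError(f"{self.patient_id}/{var}: negative value")
            clean[var] = (days, values)
        self.series = clean

    def value_near(self, variable: str, day: float,
                   tolerance: float) -> float | None:
        """Value of the visit nearest ``day`` within ``tolerance``, else None."""
        if variable not in self.series:
            return None
        days, values = self.series[variable]
        if days.size == 0:
            return None
        i = int(np.argmin(np.abs(days - day)))
        if abs(days[i] - day) > tolerance:
            return None
        return float(values[i])


def classify_lymphocytosis(series: PatientSeries,
                           m0_day: float = 0.0,
                           m3_day: float = 3 * DAYS_PER_MONTH,
                           tolerance_days: float = DEFAULT_TOLERANCE_DAYS) -> str:
    """Classify one patient as ``pHL``, ``tHL`` or ``undetermined``.

    pHL requires the ALC at the visit nearest month 3 to strictly exceed the
    ALC at the visit nearest month 0; a missing visit within tolerance yields
    ``undetermined``.  The rule is scale-free (invariant to ALC unit changes).
    """
    if "ALC" not in series.series:
        raise SchemaError(f"{series.patient_id}: no ALC series")
    a0 = series.value_near("ALC", m0_day, tolerance_days)
    a3 = series.value_near("ALC", m3_day, tolerance_days)
    if a0 is None or a3 is None:
        return "undetermined"
    return "pHL" if a3 > a0 else "tHL"


def percent_change(series: PatientSeries, variable: str):
    """Per-visit percent change from the first observation of ``variable``."""
    if variable not in series.series:
        raise SchemaError(f"{series.patient_id}: no {variable} series")
    days, values = series.series[variable]
    if values.size == 0 or values[0] <= 0:
        raise ValidationError(
            f"{series.patient_id}/{variable}: nonpositive baseline")
    return days.copy(), 100.0 * (values - values[0]) / values[0]


def ball_score(covariates: Mapping[str, float]):
    """BALL prognostic score: one point each for beta2-microglobulin > 5 mg/L,
    hemoglobin < 110 g/L, LDH above the upper limit of normal, and last
    therapy started less than 24 months ago.  Returns (score, band)."""
    required = ("b2m_mg_per_L", "hb_g_per_L", "ldh_uln_ratio",
                "months_since_last_therapy")
    missing = [k for k in required if k not in covariates
               or covariates[k] is None
               or (isinstance(covariates[k], float) and np.isnan(covariates[k]))]
    if missing:
        raise MissingCovariateError(f"missing covariate(s): {missing}")
    score = int(covariates["b2m_mg_per_L"] > 5.0) \
        + int(covariates["hb_g_per_L"] < 110.0) \
        + int(covariates["ldh_uln_ratio"] > 1.0) \
        + int(covariates["months_since_last_therapy"] < 24.0)
    for band, (lo, hi) in BALL_BANDS.items():
        if lo <= score <= hi:
            return score, band
    raise ValidationError(f"score {score} outside banding")  # pragma: no cover


def summarize_group(cohort: Iterable[PatientSeries], variable: str,
                    statistic: str = "median",
                    percent: bool = False) -> pd.DataFrame:
    """Per-visit-day, per-group summary of ``variable`` across patients.

    With ``percent=True`` the summary is taken over per-patient percent
    changes from baseline.  Patients without a group label are skipped.
    """
    if statistic not in ("median", "mean"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    rows = []
    for p in cohort:
        if p.group not in ("tHL", "pHL"):
            continue
        if variable not in p.series:
            continue
        if percent:
            days, vals = percent_change(p, variable)
        else:
            days, vals = p.series[variable]
        for d, v in zip(days, vals):
            rows.append((p.group, float(d), float(v)))
    if not rows:
        raise ValidationError("empty cohort or variable never observed")
    df = pd.DataFrame(rows, columns=["group", "time_days", "value"])
    agg = "median" if statistic == "median" else "mean"
    out = (df.groupby(["group", "time_days"])["value"]
           .agg([agg, "count"]).reset_index()
           .rename(columns={agg: statistic, "count": "n"}))
    return out


def classify_cohort(cohort: Iterable[PatientSeries],
                    tolerance_days: float = DEFAULT_TOLERANCE_DAYS) -> pd.DataFrame:
    """Classification table for a cohort; logs and excludes undetermined."""
    rows = []
    for p in cohort:
        label = classify_lymphocytosis(p, tolerance_days=tolerance_days)
        a0 = p.value_near("ALC", 0.0, tolerance_days)
        a3 = p.value_near("ALC", 3 * DAYS_PER_MONTH, tolerance_days)
        if label == "undetermined":
            logger.warning("patient %s undetermined (missing M0 or M3 ALC); "
                           "excluded from group analyses", p.patient_id)
        rows.append((p.patient_id, label, a0, a3))
    return pd.DataFrame(rows, columns=["patient_id", "group_assigned",
                                       "alc_m0", "alc_m3"])


def compare_groups(values_a, values_b, test: str = "mann_whitney") -> _stats.TestResult:
    """Two-group comparison; delegates to the stats layer."""
    if test == "mann_whitney":
        return _stats.mann_whitney_u(values_a, values_b)
    if test == "chi_square":
        # each argument is one row of counts of a 2x2 table
        return _stats.chi_square_2x2(np.vstack([values_a, values_b]))
    raise ValidationError(f"unknown test {test!r}")
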