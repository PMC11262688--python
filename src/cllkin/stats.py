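"""Elementary two-group tests used throughout the analyses.

Small-sample comparisons between the transient (tHL) and prolonged (pHL)
hyperlymphocytosis groups use the two-tailed Mann-Whitney U test; paired
in-vitro measurements use the paired Student t test; group proportions across
cohorts use the Pearson chi-square on a 2x2 table; and covariate coefficients
from the population model are tested with a Wald z test.

The Mann-Whitney implementation carries an exact mode that enumerates the
full permutation null over all C(n_x+n_y, n_x) group assignments (feasible up
to combined sample size 14) so the normal approximation can be validated
against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateVarianceError, ValidationError

#: Combined sample size up to which exact enumeration is used in auto mode.
EXACT_ENUMERATION_LIMIT = 14


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value outside [0,1]: {self.p_value}")


def _ranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _u_from_ranksum(rank_sum_x: float, nx: int) -> float:
    return rank_sum_x - nx * (nx + 1) / 2.0


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-tailed Mann-Whitney U test.

    ``exact`` enumerates the permutation null on average ranks (ties allowed);
    ``normal`` uses the tie-corrected normal approximation with continuity
    correction; ``auto`` picks exact when n_x + n_y <= 14.  The reported
    statistic is min(U_x, U_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValidationError("both samples must be nonempty")
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if nx + ny <= EXACT_ENUMERATION_LIMIT else "normal"

    pooled = np.concatenate([x, y])
    ranks = _ranks(pooled)
    u_x = _u_from_ranksum(ranks[:nx].sum(), nx)
    u_y = nx * ny - u_x
    u_min = min(u_x, u_y)

    if mode == "exact":
        n = nx + ny
        # null distribution of U_x over all label assignments on fixed ranks
        us = np.array([
            _u_from_ranksum(sum(ranks[list(idx)]), nx)
            for idx in combinations(range(n), nx)
        ])
        total = comb(n, nx)
        eps = 1e-9
        p_lo = np.sum(us <= u_x + eps) / total
        p_hi = np.sum(us >= u_x - eps) / total
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return TestResult(u_min, p, "mann_whitney_exact", (nx, ny))

    # tie-corrected normal approximation with continuity correction
    mean_u = nx * ny / 2.0
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return TestResult(u_min, 1.0, "mann_whitney_normal", (nx, ny))
    z = (np.abs(u_x - mean_u) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(u_min, p, "mann_whitney_normal", (nx, ny))


def paired_t(x, y) -> TestResult:
    """Two-tailed paired Student t test on differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired samples must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise ValidationError("paired t test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("all paired differences are identical")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(t, min(1.0, p), "paired_t", (n,))


def chi_square_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 count table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0) or np.any(obs != np.floor(obs)):
        raise ValidationError("table must be 2x2 nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff**2 / expected))
    p = sps.chi2.sf(chi2, df=1)
    tag = "chi_square_yates" if correction else "chi_square"
    return TestResult(chi2, min(1.0, p), tag, tuple(int(v) for v in row))


def wald_z(beta_hat: float, se: float) -> TestResult:
    """Two-tailed Wald z test of a coefficient against zero."""
    if not np.isfinite(se) or se <= 0:
        raise ValidationError("standard error must be positive and finite")
    z = beta_hat / se
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(z, min(1.0, p), "wald_z", (1,))
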