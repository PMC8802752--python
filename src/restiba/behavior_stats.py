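"""Demographic comparisons, reverter classification, partial correlations, FDR.

These are the table-level statistics of the study design: pooled two-sample
t-tests and uncorrected Pearson chi-square for demographic rows, a
logical-memory-based rule for classifying cognitive reverters, partial
correlations (residual method) between cluster metric values and cognitive
scale scores, and Benjamini-Hochberg FDR over the resulting p values.

The pooled t-test accepts either raw samples or (n, mean, SD) summary rows so
published tables can be checked directly.  The chi-square deliberately omits
the Yates continuity correction, matching the convention that reproduces the
published sex-row p value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PartialCorrResult",
    "pooled_two_sample_t",
    "pooled_t_from_summary",
    "chi_square_independence",
    "partial_correlation",
    "bh_fdr",
    "classify_reverter",
    "cluster_score_correlations",
]


@dataclass
class PartialCorrResult:
    region: str
    scale: str
    r: float
    p: float
    p_fdr: float | None
    covariates: tuple[str, ...]
    n: int


def pooled_t_from_summary(n1: int, mean1: float, sd1: float,
                          n2: int, mean2: float, sd2: float) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df, two-tailed p) with df = n1 + n2 - 2.  A zero pooled
    variance with unequal means yields p = 0 (documented edge).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        return float(np.sign(mean1 - mean2) * np.inf), df, 0.0
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def pooled_two_sample_t(group1, group2) -> tuple[float, int, float]:
    """Pooled two-sample t on raw values; equals the summary form exactly."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    return pooled_t_from_summary(len(x), x.mean(), x.std(ddof=1),
                                 len(y), y.mean(), y.std(ddof=1))


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(stat), float(p)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Partial correlation via the residual method.

    x and y are each regressed (OLS with intercept) on the covariate matrix;
    the Pearson correlation of the two residual vectors is returned with a p
    value from the t transform at df = n - 2 - n_covariates.  An empty
    covariate set reduces to the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or (np.size(covariates) == 0):
        c = np.ones((n, 1))
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        c = np.column_stack([np.ones(n), cov])
        k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    rx = x - c @ np.linalg.lstsq(c, x, rcond=None)[0]
    ry = y - c @ np.linalg.lstsq(c, y, rcond=None)[0]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx <= 1e-12 * max(np.linalg.norm(x), 1.0) or \
            sy <= 1e-12 * max(np.linalg.norm(y), 1.0):
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p values, rejection mask at q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def classify_reverter(lm_trajectory, mmse_trajectory, lm_cutoff: float,
                      mmse_cutoff: float = 24.0) -> tuple[bool, int | None]:
    """Logical-memory reversion rule.

    A subject is a reverter iff the first-visit LM score is below the
    education-adjusted normal cutoff (MCI range) and some later visit has
    LM >= cutoff with MMSE strictly greater than ``mmse_cutoff`` at that same
    visit.  Returns (is_reverter, earliest qualifying visit index).  Visits
    with a missing LM or MMSE score are skipped (logged).
    """
    lm = np.asarray(lm_trajectory, dtype=float)
    mmse = np.asarray(mmse_trajectory, dtype=float)
    if lm.shape != mmse.shape or lm.ndim != 1 or len(lm) < 2:
        raise ValueError("need aligned LM and MMSE trajectories with >= 2 visits")
    if np.isnan(lm[0]):
        raise ValueError("baseline LM score is required")
    if lm[0] >= lm_cutoff:
        return False, None  # never in the MCI range
    for visit in range(1, len(lm)):
        if np.isnan(lm[visit]) or np.isnan(mmse[visit]):
            logger.info("visit %d skipped: missing score", visit)
            continue
        if lm[visit] >= lm_cutoff and mmse[visit] > mmse_cutoff:
            return True, visit
    return False, None


def cluster_score_correlations(values: pd.DataFrame, scores: pd.DataFrame,
                               covariates: pd.DataFrame | None = None,
                               q: float = 0.05) -> pd.DataFrame:
    """Partial correlations of every (region column, scale column) pair.

    ``values`` holds per-subject cluster mean metric values (one column per
    region), ``scores`` the cognitive scale scores, ``covariates`` the
    numeric covariate columns (site already dummy-coded by the caller).
    Missing scores are dropped pairwise (logged).  Returns a tidy frame with
    BH-FDR adjusted p values over all tested pairs.
    """
    rows = []
    cov_names = tuple(covariates.columns) if covariates is not None else ()
    for region in values.columns:
        for scale in scores.columns:
            x = values[region].to_numpy(dtype=float)
            y = scores[scale].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if covariates is not None:
                c = covariates.to_numpy(dtype=float)
                ok &= ~np.isnan(c).any(axis=1)
                c_ok = c[ok]
            else:
                c_ok = None
            if ok.sum() < len(x):
                logger.info("%s/%s: %d subjects dropped pairwise",
                            region, scale, int((~ok).sum()))
            r, p = partial_correlation(x[ok], y[ok], c_ok)
            rows.append({"region": region, "scale": scale, "r": r, "p": p,
                         "n": int(ok.sum()), "covariates": ",".join(cov_names)})
    out = pd.DataFrame(rows)
    if len(out):
        p_adj, _ = bh_fdr(out["p"].to_numpy(), q)
        out["p_fdr"] = p_adj
    else:
        out["p_fdr"] = []
    return out
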