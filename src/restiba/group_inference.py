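"""Voxelwise two-sample GLM and Gaussian-random-field cluster inference.

The group model is a mass-univariate OLS fit per voxel with columns
[intercept, group, mean FD, site dummies]; the group-difference t statistic
is the contrast on the group column, so positive t means the first group
(reverter-like) exceeds the second after covariate adjustment.  Continuous
covariates are mean-centred before entering the design.

Cluster-level correction follows classical random-field theory for a
Gaussianized t field: the map is thresholded two-tailed at voxel p (p/2 per
tail, positive and negative excursion sets clustered separately with
26-connectivity), residual smoothness is estimated from the standardized GLM
residuals via the variance of their spatial derivatives, and each cluster of
size k receives the corrected probability

    p_c = 1 - exp(-E[m] * P(n >= k)),      P(n >= k) = exp(-beta * k^(2/D)),

with E[m] the expected number of clusters, E[n] = E[N]/E[m] the expected
cluster size, and beta = (Gamma(D/2+1)/E[n])^(2/D)  (D = 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .core import MetricMap

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDesign",
    "StatMap",
    "SmoothnessEstimate",
    "ClusterTable",
    "build_design_matrix",
    "glm_two_sample_t",
    "estimate_smoothness",
    "grf_cluster_p",
    "grf_cluster_inference",
    "match_filter_cohort",
]

CLUSTER_COLUMNS = ["cluster_id", "size_voxels", "peak_x_mm", "peak_y_mm",
                   "peak_z_mm", "peak_t", "sign", "corrected_p"]


@dataclass
class GroupDesign:
    """Design matrix for the two-sample comparison with nuisance covariates."""

    matrix: np.ndarray            # (n_subjects, p)
    columns: list[str]
    contrast: np.ndarray          # selects the group column
    subjects: list[str]
    group: np.ndarray             # 1 = reverter-like, 0 = control

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


@dataclass
class StatMap:
    """Voxelwise t map with degrees of freedom and retained residuals."""

    t: np.ndarray                 # 3D
    df: int
    residuals: np.ndarray         # (n_subjects, x, y, z)
    mask: np.ndarray
    affine: np.ndarray


@dataclass
class SmoothnessEstimate:
    fwhm_mm: np.ndarray           # per axis
    fwhm_voxels: np.ndarray       # per axis
    resels: float
    voxel_volume_mm3: float

    @property
    def fwhm_geomean_voxels(self) -> float:
        return float(np.prod(self.fwhm_voxels) ** (1.0 / 3.0))


@dataclass
class ClusterTable:
    """GRF-surviving clusters plus the label volume they index into."""

    table: pd.DataFrame
    label_map: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.table)

    def cluster_mask(self, cluster_id: int) -> np.ndarray:
        return self.label_map == cluster_id

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design and GLM
# ---------------------------------------------------------------------------

def build_design_matrix(records: pd.DataFrame,
                        group_col: str = "group",
                        reverter_label: str = "reverter",
                        fd_col: str = "mean_fd",
                        site_col: str = "site") -> GroupDesign:
    """Columns: [intercept, group, mean FD (centred), site dummies (k-1)].

    Every site must contain both groups; otherwise the caller is directed to
    ``match_filter_cohort`` first.
    """
    records = records.reset_index(drop=True)
    group = (records[group_col] == reverter_label).to_numpy(dtype=float)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    cols = [np.ones(len(records)), group]
    names = ["intercept", "group"]
    if fd_col in records:
        fd = records[fd_col].to_numpy(dtype=float)
        if fd.std() > 0:
            cols.append(fd - fd.mean())
            names.append("mean_fd")
        else:
            logger.warning("mean FD is constant across subjects; covariate dropped")
    if site_col in records:
        sites = sorted(records[site_col].unique())
        for s in sites:
            sub = group[records[site_col] == s]
            if sub.size == 0 or sub.min() == sub.max():
                raise ValueError(
                    f"site {s!r} lacks one of the groups; run match_filter_cohort first"
                )
        for s in sites[1:]:  # reference level dropped
            cols.append((records[site_col] == s).to_numpy(dtype=float))
            names.append(f"site[{s}]")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    contrast = np.zeros(x.shape[1])
    contrast[1] = 1.0
    subjects = [str(s) for s in records.get("subject_id", records.index)]
    return GroupDesign(x, names, contrast, subjects, group.astype(int))


def glm_two_sample_t(maps: list[MetricMap] | np.ndarray, design: GroupDesign) -> StatMap:
    """Mass-univariate OLS; t for the group contrast, residuals retained."""
    if isinstance(maps[0], MetricMap):
        mask = maps[0].mask
        affine = maps[0].affine
        for m in maps[1:]:
            if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
                raise ValueError("all metric maps must share one grid and mask")
            if (m.standardized, m.smoothed) != (maps[0].standardized, maps[0].smoothed):
                raise ValueError("metric maps differ in standardization/smoothing state")
        y4 = np.stack([m.data for m in maps])
    else:
        y4 = np.asarray(maps, dtype=np.float64)
        mask = np.ones(y4.shape[1:], dtype=bool)
        affine = np.eye(4)
    x = design.matrix
    n, p = x.shape
    if y4.shape[0] != n:
        raise ValueError("number of maps must match design rows")
    if n < p + 1:
        raise ValueError("fewer subjects than design columns + 1")
    df = n - np.linalg.matrix_rank(x)

    y = y4[:, mask]  # (n, v)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    c = design.contrast
    se = np.sqrt(np.maximum(sigma2 * (c @ xtx_inv @ c), 0.0))
    # a residual variance at round-off scale means the model fits exactly: t = 0
    se_floor = 1e-12 * np.sqrt(np.maximum((y**2).mean(axis=0), 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(se > se_floor, (c @ beta) / se, 0.0)

    t3 = np.zeros(mask.shape)
    t3[mask] = t_vals
    res4 = np.zeros((n,) + mask.shape)
    res4[:, mask] = resid
    return StatMap(t3, int(df), res4, mask, affine)


# ---------------------------------------------------------------------------
# Smoothness and GRF
# ---------------------------------------------------------------------------

def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray,
                        voxel_size_mm) -> SmoothnessEstimate:
    """Per-axis FWHM from the variance of normalized residual derivatives.

    Residual images are scaled to unit variance per voxel; for a unit-variance
    Gaussian field the derivative variance lambda along an axis gives
    FWHM = sqrt(4 ln 2 / lambda) in voxel units.  The estimate is floored at
    half a voxel to keep resel counts finite on degenerate input.
    """
    residuals = np.asarray(residuals, dtype=np.float64)
    if residuals.ndim != 4 or residuals.shape[0] < 3:
        raise ValueError("need a (n>=3, x, y, z) residual stack")
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,)).copy()
    sd = residuals.std(axis=0)
    if not (sd[mask] > 0).any():
        raise ValueError("residuals are constant; smoothness undefined")
    norm = np.where(sd > 0, residuals / np.where(sd > 0, sd, 1.0), 0.0)

    fwhm_vox = np.empty(3)
    for axis in range(3):
        d = np.diff(norm, axis=axis + 1)
        m_pair = np.logical_and(
            np.take(mask, range(mask.shape[axis] - 1), axis=axis),
            np.take(mask, range(1, mask.shape[axis]), axis=axis),
        )
        valid = np.broadcast_to(m_pair, d.shape)
        lam = float((d[valid] ** 2).mean()) if valid.any() else np.nan
        if not np.isfinite(lam) or lam <= 0:
            fwhm_vox[axis] = 0.5
        else:
            fwhm_vox[axis] = max(np.sqrt(4.0 * np.log(2.0) / lam), 0.5)
    n_mask = int(mask.sum())
    resels = n_mask / float(np.prod(fwhm_vox))
    return SmoothnessEstimate(fwhm_vox * voxel_size_mm, fwhm_vox, resels,
                              float(np.prod(voxel_size_mm)))


def grf_cluster_p(size_voxels: int, z_threshold: float, n_mask_voxels: int,
                  fwhm_geomean_voxels: float, dim: int = 3) -> float:
    """Cluster-level corrected p for a cluster of ``size_voxels`` voxels."""
    u = z_threshold
    s = float(n_mask_voxels)
    w = fwhm_geomean_voxels / np.sqrt(4.0 * np.log(2.0))
    em = s * (2.0 * np.pi) ** (-(dim + 1) / 2.0) * w**(-dim) * u**(dim - 1) * np.exp(-u**2 / 2.0)
    en = s * stats.norm.sf(u) / em
    beta = (special.gamma(dim / 2.0 + 1.0) / en) ** (2.0 / dim)
    p_size = np.exp(-beta * float(size_voxels) ** (2.0 / dim))
    return float(-np.expm1(-em * p_size))


def _gaussianize_t(t_map: np.ndarray, df: int) -> np.ndarray:
    """Map t values to z values with the same tail probability (sign-aware)."""
    at = np.abs(t_map)
    z = stats.norm.isf(np.clip(stats.t.sf(at, df), 1e-300, 1.0))
    return np.sign(t_map) * z


_CONNECTIVITY = {6: ndimage.generate_binary_structure(3, 1),
                 18: ndimage.generate_binary_structure(3, 2),
                 26: ndimage.generate_binary_structure(3, 3)}


def grf_cluster_inference(stat: StatMap, smooth: SmoothnessEstimate,
                          voxel_p: float = 0.05, cluster_p: float = 0.05,
                          two_tailed: bool = True,
                          connectivity: int = 26) -> ClusterTable:
    """Cluster-level GRF correction of a t map.

    Positive and negative excursion sets are thresholded at voxel p/2 each
    (two-tailed), clustered with the requested connectivity, and clusters with
    corrected p < cluster_p are retained.  An empty table is a valid result.
    """
    if stat.df < 1:
        raise ValueError("need at least 1 degree of freedom")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    tail_p = voxel_p / 2.0 if two_tailed else voxel_p
    u = float(stats.norm.isf(tail_p))
    z = _gaussianize_t(stat.t, stat.df)
    t_thr = float(stats.t.isf(tail_p, stat.df))
    n_mask = int(stat.mask.sum())
    structure = _CONNECTIVITY[connectivity]

    rows = []
    label_map = np.zeros(stat.mask.shape, dtype=np.int32)
    next_id = 1
    for sign, excursion in ((1, (z >= u) & stat.mask), (-1, (-z >= u) & stat.mask)):
        labels, n_clusters = ndimage.label(excursion, structure=structure)
        for lab in range(1, n_clusters + 1):
            m = labels == lab
            k = int(m.sum())
            p_c = grf_cluster_p(k, u, n_mask, smooth.fwhm_geomean_voxels)
            if p_c < cluster_p:
                tv = stat.t * sign
                flat = np.where(m, tv, -np.inf)
                peak = np.unravel_index(int(np.argmax(flat)), flat.shape)
                peak_mm = stat.affine @ np.array([*peak, 1.0])
                rows.append({
                    "cluster_id": next_id,
                    "size_voxels": k,
                    "peak_x_mm": float(peak_mm[0]),
                    "peak_y_mm": float(peak_mm[1]),
                    "peak_z_mm": float(peak_mm[2]),
                    "peak_t": float(stat.t[peak]),
                    "sign": sign,
                    "corrected_p": p_c,
                })
                label_map[m] = next_id
                next_id += 1
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    logger.info("GRF: %d surviving clusters (t threshold %.3f, z %.3f)",
                len(table), t_thr, u)
    return ClusterTable(table, label_map)


# ---------------------------------------------------------------------------
# Cohort filtering (site coverage + motion QC)
# ---------------------------------------------------------------------------

def match_filter_cohort(records: pd.DataFrame,
                        group_col: str = "group",
                        site_col: str = "site",
                        qc_col: str = "motion_include") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop motion-QC failures, then all subjects at any single-group site.

    Returns (surviving records, exclusion log with columns subject_id/reason).
    """
    records = records.reset_index(drop=True)
    excluded = []
    kept = records
    if qc_col in kept:
        bad = kept[~kept[qc_col].astype(bool)]
        for _, row in bad.iterrows():
            excluded.append({"subject_id": row.get("subject_id"), "reason": "motion"})
        kept = kept[kept[qc_col].astype(bool)]
    groups_per_site = kept.groupby(site_col)[group_col].nunique()
    n_groups = records[group_col].nunique()
    bad_sites = groups_per_site[groups_per_site < n_groups].index
    for _, row in kept[kept[site_col].isin(bad_sites)].iterrows():
        excluded.append({"subject_id": row.get("subject_id"), "reason": "site-coverage"})
    kept = kept[~kept[site_col].isin(bad_sites)].reset_index(drop=True)
    log = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    if len(log):
        logger.info("match_filter_cohort excluded %d subjects", len(log))
    return kept, log
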