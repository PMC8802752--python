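"""The five intrinsic-activity metrics: ALFF, fALFF, PerAF, ReHo, DC.

Conventions
-----------
* Amplitude spectrum: for a length-n series the one-sided amplitude at bin k
  is ``2|X_k|/n`` (``|X_k|/n`` for the DC and, when n is even, the Nyquist
  bin), so a pure sinusoid of amplitude A contributes amplitude A at its bin.
  ALFF is the mean amplitude over bins with band_low <= f <= band_high; fALFF
  is the in-band amplitude sum divided by the amplitude sum over all positive
  frequencies (DC excluded — the mean intensity is not a fluctuation).
* PerAF is the mean absolute deviation from the temporal mean, as a
  percentage of that mean; it therefore needs the mean-preserving signal and
  is evaluated on the filtered series with the stored voxel mean added back.
* ReHo is Kendall's coefficient of concordance W of a voxel's time series
  with its K-1 nearest neighbours (K in {7, 19, 27}), ranks over time with
  average ties.  At mask edges only in-mask neighbours enter and K is reduced
  to the actual series count, which keeps W in [0, 1] there instead of
  deflating it.
* DC counts, for each voxel, the other in-mask voxels whose Pearson
  correlation with it exceeds r0 (strict; positive correlations only).  The
  full voxel-by-voxel correlation matrix is never materialized: correlations
  are accumulated block-wise.

Metric maps are standardized by dividing by the global (in-mask) mean — the
"m-map" convention, so the standardized map has in-mask mean 1 — and smoothed
afterwards with a Gaussian kernel specified by its FWHM in mm.  Smoothing
deliberately happens after metric computation: smoothing first would inflate
local inter-voxel correlation and bias ReHo and DC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import BoldSeries, MetricMap, PipelineOrderError
from .temporal_preprocess import restore_mean

logger = logging.getLogger(__name__)

__all__ = [
    "MetricConfig",
    "amplitude_spectrum",
    "compute_alff",
    "compute_falff",
    "compute_peraf",
    "peraf_series",
    "compute_reho",
    "kendall_w",
    "compute_dc",
    "standardize_by_global_mean",
    "gaussian_smooth",
    "compute_all_metrics",
]

_REHO_K = {
    7: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1],
    19: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if abs(dx) + abs(dy) + abs(dz) <= 2],
    27: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)],
}


@dataclass
class MetricConfig:
    """Metric parameters; defaults follow the reference acquisition protocol."""

    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    reho_k: int = 27
    dc_threshold: float = 0.25
    dc_mode: str = "binarized"
    smooth_fwhm_mm: float = 4.0
    standardization: str = "global_mean"  # or "zscore"

    def __post_init__(self) -> None:
        if self.reho_k not in (7, 19, 27):
            raise ValueError("ReHo neighbourhood K must be 7, 19 or 27")
        if not (0.0 < self.dc_threshold < 1.0):
            raise ValueError("DC threshold must lie in (0, 1)")
        if self.dc_mode not in ("binarized", "weighted"):
            raise ValueError("DC mode must be 'binarized' or 'weighted'")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be >= 0")


# ---------------------------------------------------------------------------
# Amplitude metrics (unfiltered input)
# ---------------------------------------------------------------------------

def amplitude_spectrum(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """One-sided amplitude spectrum with the sinusoid-amplitude normalization."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[axis]
    amp = np.abs(np.fft.rfft(x, axis=axis)) * (2.0 / n)
    amp_moved = np.moveaxis(amp, axis, -1)
    amp_moved[..., 0] /= 2.0
    if n % 2 == 0:
        amp_moved[..., -1] /= 2.0
    return amp


def _check_amplitude_input(series: BoldSeries) -> None:
    if series.filtered:
        raise PipelineOrderError(
            "ALFF/fALFF need the unfiltered series: band-pass filtering is part "
            "of their own definition"
        )


def compute_alff(
    series: BoldSeries, band_low_hz: float = 0.01, band_high_hz: float = 0.08
) -> MetricMap:
    """Mean square-root power-spectrum amplitude over the low-frequency band."""
    _check_amplitude_input(series)
    freqs = np.fft.rfftfreq(series.n_volumes, d=series.tr_s)
    in_band = (freqs >= band_low_hz) & (freqs <= band_high_hz)
    in_band[0] = False
    if not in_band.any():
        raise ValueError("no DFT bin falls inside the requested band")
    amp = amplitude_spectrum(series.data[series.mask])
    vals = amp[:, in_band].mean(axis=1)
    out = np.zeros(series.grid_shape)
    out[series.mask] = vals
    return MetricMap(out, "ALFF", series.mask, series.affine)


def compute_falff(
    series: BoldSeries, band_low_hz: float = 0.01, band_high_hz: float = 0.08
) -> MetricMap:
    """In-band amplitude sum over the whole positive-frequency amplitude sum."""
    _check_amplitude_input(series)
    freqs = np.fft.rfftfreq(series.n_volumes, d=series.tr_s)
    in_band = (freqs >= band_low_hz) & (freqs <= band_high_hz)
    in_band[0] = False
    amp = amplitude_spectrum(series.data[series.mask])
    num = amp[:, in_band].sum(axis=1)
    den = amp[:, 1:].sum(axis=1)  # DC excluded
    vals = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out = np.zeros(series.grid_shape)
    out[series.mask] = vals
    return MetricMap(out, "fALFF", series.mask, series.affine)


# ---------------------------------------------------------------------------
# PerAF (filtered input with restored mean)
# ---------------------------------------------------------------------------

def peraf_series(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """PerAF of raw-scale series: 100 * mean|X_i - mu| / mu (0 where mu <= 0)."""
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=axis)
    mad = np.abs(x - np.expand_dims(mu, axis)).mean(axis=axis)
    return np.where(mu > 0, 100.0 * np.divide(mad, mu, out=np.zeros_like(mad),
                                              where=mu > 0), 0.0)


def compute_peraf(series: BoldSeries) -> MetricMap:
    """Percent amplitude of fluctuation on the mean-preserving filtered signal.

    The band-passed residual has zero temporal mean, so the per-voxel mean
    captured before detrending is added back; voxels whose restored mean is
    not positive are set to 0 and counted in the log.
    """
    if series.filtered or series.detrended:
        if series.voxel_mean is None:
            raise ValueError(
                "PerAF on a mean-removed series requires the stored voxel mean"
            )
        data = restore_mean(series)
    else:
        data = series.data
    vals = peraf_series(data[series.mask])
    mu = data[series.mask].mean(axis=-1)
    n_bad = int((mu <= 0).sum())
    if n_bad:
        logger.warning("PerAF: %d in-mask voxels with non-positive mean set to 0", n_bad)
    out = np.zeros(series.grid_shape)
    out[series.mask] = vals
    return MetricMap(out, "PerAF", series.mask, series.affine)


# ---------------------------------------------------------------------------
# ReHo (filtered input)
# ---------------------------------------------------------------------------

def kendall_w(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K series over n time points.

    ``series_set`` has shape (K, n).  Ranks are taken over time with average
    ties; W = (sum R_i^2 - n Rbar^2) / (K^2 (n^3 - n) / 12).
    """
    k, n = series_set.shape
    ranks = stats.rankdata(series_set, method="average", axis=1)
    r_i = ranks.sum(axis=0)
    rbar = k * (n + 1) / 2.0
    num = (r_i**2).sum() - n * rbar**2
    den = k**2 * (n**3 - n) / 12.0
    return float(num / den)


def _check_filtered_input(series: BoldSeries, metric: str) -> None:
    if not series.filtered:
        raise PipelineOrderError(f"{metric} requires the band-pass filtered series")


def compute_reho(series: BoldSeries, k: int = 27) -> MetricMap:
    """Regional homogeneity: Kendall's W over the K-voxel neighbourhood.

    Implemented with shifted rank volumes so the whole map is vectorized; at
    mask edges K is reduced to the number of in-mask series (centre included).
    """
    _check_filtered_input(series, "ReHo")
    if k not in _REHO_K:
        raise ValueError("K must be 7, 19 or 27")
    if series.n_volumes < 3:
        raise ValueError("ReHo needs at least 3 time points")
    mask = series.mask
    n_t = series.n_volumes
    ranks = np.zeros(series.data.shape)
    ranks[mask] = stats.rankdata(series.data[mask], method="average", axis=-1)

    shape = series.grid_shape
    pad_ranks = np.pad(ranks, ((1, 1), (1, 1), (1, 1), (0, 0)))
    pad_mask = np.pad(mask.astype(np.float64), 1)
    r_sum = np.zeros(series.data.shape)  # R_i per voxel and time
    k_count = np.zeros(shape)
    for dx, dy, dz in _REHO_K[k]:
        sl = (slice(1 + dx, 1 + dx + shape[0]),
              slice(1 + dy, 1 + dy + shape[1]),
              slice(1 + dz, 1 + dz + shape[2]))
        r_sum += pad_ranks[sl]
        k_count += pad_mask[sl]

    rbar = k_count[..., None] * (n_t + 1) / 2.0
    num = (r_sum**2).sum(axis=-1) - n_t * (rbar[..., 0] ** 2) * 1.0
    # note: sum_t rbar^2 = n * rbar^2 since rbar is time-constant
    den = k_count**2 * (n_t**3 - n_t) / 12.0
    w = np.zeros(shape)
    valid = mask & (k_count >= 2)
    w[valid] = num[valid] / den[valid]
    w[mask & (k_count < 2)] = 0.0
    w = np.clip(w, 0.0, 1.0)
    return MetricMap(np.where(mask, w, 0.0), "ReHo", mask, series.affine)


# ---------------------------------------------------------------------------
# Degree centrality (filtered input)
# ---------------------------------------------------------------------------

def compute_dc(
    series: BoldSeries,
    r_threshold: float = 0.25,
    mode: str = "binarized",
    block_size: int = 2048,
) -> MetricMap:
    """Voxel-wise degree centrality over the in-mask correlation graph.

    Binarized mode counts voxels j != i with r_ij > r_threshold (strict,
    positive side only); weighted mode sums those r_ij.  Zero-variance voxels
    correlate 0 with everything and are never counted.  Correlations are
    computed block against all, so memory stays at O(block * n_voxels).
    """
    _check_filtered_input(series, "DC")
    if series.n_volumes < 3:
        raise ValueError("DC needs at least 3 time points")
    if mode not in ("binarized", "weighted"):
        raise ValueError("mode must be 'binarized' or 'weighted'")
    mask = series.mask
    x = series.data[mask]  # (v, t)
    n_v = x.shape[0]
    if n_v < 2:
        raise ValueError("DC needs at least 2 in-mask voxels")
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc**2).sum(axis=1))
    zero_var = norm == 0
    if zero_var.any():
        logger.warning("DC: %d zero-variance voxels treated as uncorrelated", zero_var.sum())
    safe = np.where(zero_var, 1.0, norm)
    z = (xc / safe[:, None]).astype(np.float64)
    z[zero_var] = 0.0

    dc = np.zeros(n_v)
    for start in range(0, n_v, block_size):
        stop = min(start + block_size, n_v)
        r_blk = z[start:stop] @ z.T  # (b, n_v)
        hits = r_blk > r_threshold
        # exclude self-correlation
        idx = np.arange(start, stop)
        hits[np.arange(stop - start), idx] = False
        if mode == "binarized":
            dc[start:stop] = hits.sum(axis=1)
        else:
            dc[start:stop] = np.where(hits, r_blk, 0.0).sum(axis=1)
    out = np.zeros(series.grid_shape)
    out[mask] = dc
    return MetricMap(out, "DC", mask, series.affine)


# ---------------------------------------------------------------------------
# Standardization and smoothing
# ---------------------------------------------------------------------------

def standardize_by_global_mean(metric: MetricMap, mode: str = "global_mean") -> MetricMap:
    """Standardize an unsmoothed metric map.

    ``global_mean`` divides by the in-mask mean (m-map convention; the result
    has in-mask mean 1 and the operation is idempotent).  ``zscore`` subtracts
    the in-mask mean and divides by the in-mask SD.
    """
    if metric.smoothed:
        raise PipelineOrderError("standardize before smoothing")
    vals = metric.in_mask()
    if mode == "global_mean":
        g = vals.mean()
        if g == 0:
            raise ValueError("global in-mask mean is zero; cannot standardize")
        out = np.where(metric.mask, metric.data / g, 0.0)
    elif mode == "zscore":
        sd = vals.std()
        if sd == 0:
            raise ValueError("in-mask SD is zero; cannot z-standardize")
        out = np.where(metric.mask, (metric.data - vals.mean()) / sd, 0.0)
    else:
        raise ValueError("mode must be 'global_mean' or 'zscore'")
    return MetricMap(out, metric.name, metric.mask, metric.affine,
                     standardized=True, smoothed=False)


def gaussian_smooth(metric: MetricMap, fwhm_mm: float,
                    voxel_size_mm: float | None = None) -> MetricMap:
    """Separable Gaussian smoothing on the full grid, then re-masked.

    sigma (voxels) = fwhm / (voxel_size * 2 sqrt(2 ln 2)).  Smoothing twice is
    an order violation and raises.
    """
    if metric.smoothed:
        raise PipelineOrderError("map already smoothed; smoothing twice is not allowed")
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm_mm == 0:
        data = metric.data.copy()
    else:
        vs = np.full(3, voxel_size_mm) if voxel_size_mm else metric.voxel_size_mm
        sigma = fwhm_mm / (vs * 2.0 * np.sqrt(2.0 * np.log(2.0)))
        data = ndimage.gaussian_filter(metric.data, sigma=sigma)
    return MetricMap(np.where(metric.mask, data, 0.0), metric.name, metric.mask,
                     metric.affine, standardized=metric.standardized, smoothed=True)


def compute_all_metrics(
    unfiltered: BoldSeries,
    filtered: BoldSeries,
    config: MetricConfig | None = None,
) -> dict[str, MetricMap]:
    """All five metrics, standardized and smoothed, plus the unstandardized
    (smoothed) PerAF branch kept for group comparison.

    Returns a dict keyed by map suffix, e.g. ``ALFF_std_sm`` and ``PerAF_sm``.
    """
    cfg = config or MetricConfig()
    raw = {
        "ALFF": compute_alff(unfiltered, cfg.band_low_hz, cfg.band_high_hz),
        "fALFF": compute_falff(unfiltered, cfg.band_low_hz, cfg.band_high_hz),
        "PerAF": compute_peraf(filtered),
        "ReHo": compute_reho(filtered, cfg.reho_k),
        "DC": compute_dc(filtered, cfg.dc_threshold, cfg.dc_mode),
    }
    out: dict[str, MetricMap] = {}
    for name, m in raw.items():
        std = standardize_by_global_mean(m, cfg.standardization)
        out[f"{name}_std_sm"] = gaussian_smooth(std, cfg.smooth_fwhm_mm)
    # unstandardized PerAF is also carried into group comparisons
    out["PerAF_sm"] = gaussian_smooth(raw["PerAF"], cfg.smooth_fwhm_mm)
    return out
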