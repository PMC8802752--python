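"""Temporal preprocessing of masked 4D BOLD data.

The chain mirrors the standard volumetric resting-state workflow: discard the
initial volumes acquired before signal equilibrium, remove the per-voxel
linear trend, regress out the Friston-24 motion expansion together with mean
white-matter and cerebrospinal-fluid signals, and finally apply an ideal
(frequency-domain boxcar) band-pass filter over 0.01-0.08 Hz.  The
preprocessed-but-unfiltered series is kept alongside the filtered one because
the amplitude metrics (ALFF/fALFF) need the full spectrum, while PerAF, ReHo
and DC consume the filtered series.

Motion quality control follows the conventional exclusion rule: a subject is
excluded when any volume exceeds 3 mm of translation on any axis or 3 degrees
of rotation about any axis (strict inequality).  Framewise displacement uses
the Power formulation with a 50 mm head radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import BoldSeries, MotionTrace, PipelineOrderError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocConfig",
    "NuisanceSet",
    "discard_initial_volumes",
    "linear_detrend",
    "friston24_expand",
    "extract_nuisance_signals",
    "build_nuisance_set",
    "nuisance_regress",
    "ideal_bandpass",
    "framewise_displacement",
    "mean_framewise_displacement",
    "motion_qc",
    "restore_mean",
    "preprocess_subject",
]


@dataclass
class PreprocConfig:
    """Temporal preprocessing parameters (defaults follow the reference acquisition protocol)."""

    n_discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    motion_limit_mm: float = 3.0
    motion_limit_deg: float = 3.0
    head_radius_mm: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 <= band_low < band_high")
        if self.motion_limit_mm <= 0 or self.motion_limit_deg <= 0:
            raise ValueError("motion limits must be positive")
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")


@dataclass
class NuisanceSet:
    """Nuisance regressor matrix (time x regressors) with column labels."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("nuisance matrix columns must match labels")


def discard_initial_volumes(series: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (scanner equilibration period)."""
    if series.volumes_discarded:
        raise PipelineOrderError("initial volumes already discarded")
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if series.n_volumes <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes: series too short"
        )
    out = series.with_data(series.data[..., n_discard:], volumes_discarded=True)
    logger.info("discarded %d initial volumes; %d remain", n_discard, out.n_volumes)
    return out


def linear_detrend(series: BoldSeries) -> BoldSeries:
    """Remove the per-voxel least-squares line over time (mean and slope).

    The temporal mean that detrending removes is stashed in ``voxel_mean`` so
    PerAF can later be evaluated on the mean-preserving signal.
    """
    if not series.volumes_discarded:
        raise PipelineOrderError("discard initial volumes before detrending")
    if series.filtered or series.nuisance_regressed:
        raise PipelineOrderError("detrend must precede regression and filtering")
    if series.n_volumes < 3:
        raise ValueError("need at least 3 time points to detrend")
    mean = series.voxel_mean
    if mean is None:
        mean = series.data.mean(axis=-1)
    detrended = signal.detrend(series.data, axis=-1, type="linear")
    out = series.with_data(detrended, detrended=True)
    out.voxel_mean = mean
    return out


def friston24_expand(motion: MotionTrace) -> np.ndarray:
    """Friston-24 motion expansion.

    For each of the 6 rigid-body parameters p the columns are
    ``[p(t), p(t)^2, p(t-1), p(t-1)^2]`` (24 columns in total, grouped per
    parameter).  The lagged series is zero-padded at t=0.
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 volumes for the lagged expansion")
    p = motion.params
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    cols = []
    for j in range(6):
        cols.extend([p[:, j], p[:, j] ** 2, lag[:, j], lag[:, j] ** 2])
    return np.column_stack(cols)


def extract_nuisance_signals(
    series: BoldSeries, wm_mask: np.ndarray, csf_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-volume spatial mean over the WM and CSF masks."""
    courses = []
    for name, m in (("WM", wm_mask), ("CSF", csf_mask)):
        m = np.asarray(m, dtype=bool)
        if m.shape != series.grid_shape:
            raise ValueError(f"{name} mask shape does not match the BOLD grid")
        if not m.any():
            raise ValueError(f"{name} mask is empty")
        courses.append(series.data[m].mean(axis=0))
    return courses[0], courses[1]


def build_nuisance_set(
    series: BoldSeries, motion: MotionTrace, wm_mask: np.ndarray, csf_mask: np.ndarray
) -> NuisanceSet:
    """Assemble Friston-24 + WM + CSF regressors aligned to the series length."""
    if motion.n_volumes != series.n_volumes:
        raise ValueError(
            f"motion trace length {motion.n_volumes} != series length {series.n_volumes}"
        )
    f24 = friston24_expand(motion)
    wm, csf = extract_nuisance_signals(series, wm_mask, csf_mask)
    labels = []
    for j, pname in enumerate(["tx", "ty", "tz", "rx", "ry", "rz"]):
        labels += [pname, f"{pname}^2", f"{pname}_lag", f"{pname}_lag^2"]
    labels += ["wm", "csf"]
    return NuisanceSet(np.column_stack([f24, wm, csf]), labels)


def _drop_collinear(design: np.ndarray, labels: list[str], tol: float = 1e-10):
    """Greedy left-to-right drop of columns that do not increase matrix rank."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > len(keep):
            keep.append(j)
        else:
            dropped.append(labels[j])
    if dropped:
        logger.warning("dropped collinear nuisance columns: %s", ", ".join(dropped))
    return design[:, keep], [labels[j] for j in keep]


def nuisance_regress(series: BoldSeries, nuisance: NuisanceSet) -> BoldSeries:
    """Replace each voxel series by its OLS residual on [intercept | nuisance]."""
    if not series.detrended:
        raise PipelineOrderError("detrend before nuisance regression")
    if series.filtered:
        raise PipelineOrderError("nuisance regression must precede filtering")
    n_t = series.n_volumes
    if nuisance.matrix.shape[0] != n_t:
        raise ValueError("nuisance rows must match the number of volumes")
    design = np.column_stack([np.ones(n_t), nuisance.matrix])
    labels = ["intercept"] + list(nuisance.labels)
    design, _ = _drop_collinear(design, labels)
    y = series.data[series.mask].T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    out_data = np.zeros_like(series.data)
    out_data[series.mask] = resid.T
    return series.with_data(out_data, nuisance_regressed=True)


def ideal_bandpass(series: BoldSeries, low_hz: float, high_hz: float) -> BoldSeries:
    """Ideal (DFT boxcar) band-pass: keep bins with low <= f <= high, zero DC.

    The boxcar convention matches the REST/DPABI toolchain and makes in-band
    pass-through and out-of-band rejection bin-exact, which the amplitude
    metrics rely on.
    """
    if not series.nuisance_regressed:
        raise PipelineOrderError("nuisance regression must precede band-pass filtering")
    if series.filtered:
        # Re-filtering is a projection; allow it (idempotence) but keep flags.
        pass
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low < high")
    if high_hz >= series.nyquist_hz:
        raise ValueError(
            f"band edge {high_hz} Hz >= Nyquist {series.nyquist_hz:.4f} Hz for TR {series.tr_s}s"
        )
    n_t = series.n_volumes
    freqs = np.fft.rfftfreq(n_t, d=series.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False  # DC always removed
    spec = np.fft.rfft(series.data, axis=-1)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=n_t, axis=-1)
    return series.with_data(out, filtered=True)


def framewise_displacement(
    motion: MotionTrace, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Power-style framewise displacement in mm; FD(0) = 0 by convention."""
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 volumes for framewise displacement")
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def mean_framewise_displacement(motion: MotionTrace, head_radius_mm: float = 50.0) -> float:
    return float(framewise_displacement(motion, head_radius_mm).mean())


def motion_qc(
    motion: MotionTrace, limit_mm: float = 3.0, limit_deg: float = 3.0
) -> bool:
    """Return True when the subject passes (is included).

    Exclusion rule: any translation magnitude strictly above ``limit_mm`` on
    any axis, or any rotation strictly above ``limit_deg`` (rotations stored
    in radians, compared in degrees).
    """
    max_trans = np.abs(motion.translations_mm).max()
    max_rot_deg = np.degrees(np.abs(motion.rotations_rad)).max()
    return not (max_trans > limit_mm or max_rot_deg > limit_deg)


def restore_mean(series: BoldSeries) -> np.ndarray:
    """Filtered data with the pre-detrend voxel mean added back (PerAF input)."""
    if series.voxel_mean is None:
        raise ValueError("series carries no stored voxel mean to restore")
    return series.data + series.voxel_mean[..., None]


def preprocess_subject(
    series: BoldSeries,
    motion: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    config: PreprocConfig | None = None,
) -> tuple[BoldSeries, BoldSeries, MotionTrace]:
    """Full temporal chain; returns (unfiltered, filtered, trimmed motion).

    The unfiltered output has been discarded/detrended/regressed and feeds
    ALFF and fALFF; the filtered output additionally passed the ideal
    band-pass and feeds PerAF, ReHo and DC.
    """
    config = config or PreprocConfig()
    series = discard_initial_volumes(series, config.n_discard)
    motion = motion.discard_initial(config.n_discard)
    series = linear_detrend(series)
    nuisance = build_nuisance_set(series, motion, wm_mask, csf_mask)
    unfiltered = nuisance_regress(series, nuisance)
    filtered = ideal_bandpass(unfiltered, config.band_low_hz, config.band_high_hz)
    return unfiltered, filtered, motion
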